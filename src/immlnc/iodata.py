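"""Readers, writers, preprocessing and the end-to-end pipeline driver.

On-disk conventions
-------------------
Expression matrices are TSV with genes in rows and a header row of sample
identifiers.  Gene annotation is a two-column TSV (``gene_id``, ``biotype``)
where biotype is ``lncRNA`` or ``mRNA``.  Tumor purity is a two-column TSV
(``sample_id``, ``purity``).  Gene sets use the standard GMT dialect.
Survival tables are TSV with columns ``sample_id``, ``time`` (days) and
``event`` (1 = death, 0 = censored).

All tables written by this module are round-trip stable: reading a written
file reproduces the in-memory object bit-for-bit (floats are serialized with
17 significant digits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("immlnc")

#: float format used by every table writer; 17 significant digits make the
#: decimal representation lossless for IEEE doubles, so round-trips are exact.
FLOAT_FORMAT = "%.17g"

#: Pipeline thresholds.  Defaults are the screening rules of the published
#: analysis; every stage logs the threshold it applies on entry.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "counts_are_raw": False,
    "lncres_threshold": 0.995,
    "lncres_two_sided": False,
    "weight_exponent": 0.0,
    "adjust_purity": True,
    "corr_alpha": 0.05,
    "corr_use_fdr": True,
    "hyper_p": 0.05,
    "min_overlap": 3,
    "restrict_to_universe": True,
    "k_min": 2,
    "k_max": 9,
    "n_resamples": 1000,
    "subsample_frac": 0.8,
    "ssgsea_alpha": 0.25,
    "de_p": 0.01,
    "de_lfc": 1.0,
    "cox_p": 0.05,
    "score_mode": "log_hr",
    "auc_horizons": [365, 1095, 1825],
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionBundle:
    """lncRNA and mRNA expression (log2 units) plus per-sample tumor purity.

    All three parts are aligned on the same ordered sample identifiers.
    """

    lnc_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    purity: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lnc_expr.columns)

    @property
    def n_samples(self) -> int:
        return self.lnc_expr.shape[1]

    def validate(self) -> None:
        if list(self.lnc_expr.columns) != list(self.mrna_expr.columns):
            raise ValueError("lncRNA and mRNA matrices have different sample columns")
        if list(self.purity.index) != list(self.lnc_expr.columns):
            raise ValueError("purity samples do not match expression samples")
        vals = self.purity.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("tumor purity values must lie in [0, 1]")
        for name, df in (("lncRNA", self.lnc_expr), ("mRNA", self.mrna_expr)):
            if df.index.duplicated().any():
                dup = df.index[df.index.duplicated()][0]
                raise ValueError(f"duplicate {name} gene id: {dup!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the size of the membership universe."""

    sets: dict[str, list[str]]
    universe_size: int = 0

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene set collection is empty")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(members) != len(set(members)):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
        if self.universe_size == 0:
            self.universe_size = len(self.universe())

    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


def validate_survival(table: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table (sample_id, time, event) and index it by sample."""
    required = {"sample_id", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in survival table: {dup!r}")
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    out = table.set_index("sample_id")
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def read_annotation(path: str | Path) -> pd.Series:
    ann = pd.read_csv(path, sep="\t")
    if ann.shape[1] < 2:
        raise ValueError("annotation must have gene_id and biotype columns")
    ann = ann.iloc[:, :2]
    ann.columns = ["gene_id", "biotype"]
    ann["gene_id"] = ann["gene_id"].astype(str).str.strip()
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in annotation: {dup!r}")
    bad = set(ann["biotype"]) - {"lncRNA", "mRNA"}
    if bad:
        raise ValueError(f"unknown biotypes in annotation: {sorted(bad)}")
    return ann.set_index("gene_id")["biotype"]


def read_purity(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["sample_id", "purity"]
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    return df.set_index("sample_id")["purity"].astype(float)


def read_expression(
    path: str | Path,
    annotation_path: str | Path,
    purity_path: str | Path | None = None,
) -> ExpressionBundle:
    """Read an expression TSV and split genes into lncRNA / mRNA matrices.

    Genes absent from the annotation are dropped (count logged).  A matrix
    whose header overlaps the annotated gene ids is taken to be transposed
    (samples in rows) and rejected rather than silently flipped.
    """
    expr = read_matrix(path)
    biotype = read_annotation(annotation_path)

    header_overlap = len(set(expr.columns) & set(biotype.index))
    if header_overlap > 0:
        raise ValueError(
            f"{header_overlap} header fields of {path} are annotated gene ids; "
            "the matrix appears transposed (genes must be rows, samples columns)"
        )

    known = expr.index.intersection(biotype.index)
    n_dropped = expr.shape[0] - len(known)
    if n_dropped:
        logger.info("read_expression: dropped %d unannotated genes", n_dropped)
    expr = expr.loc[known]
    kinds = biotype.loc[known]
    lnc = expr.loc[kinds == "lncRNA"]
    mrna = expr.loc[kinds == "mRNA"]

    if purity_path is not None:
        purity = read_purity(purity_path)
        missing = set(expr.columns) - set(purity.index)
        if missing:
            raise ValueError(
                f"samples missing from purity file: {sorted(missing)[:5]}"
            )
        purity = purity.loc[expr.columns]
    else:
        logger.warning("read_expression: no purity file given; assuming purity 1.0")
        purity = pd.Series(1.0, index=expr.columns, name="purity")

    return ExpressionBundle(lnc_expr=lnc, mrna_expr=mrna, purity=purity)


def preprocess(bundle: ExpressionBundle, counts_are_raw: bool = False) -> ExpressionBundle:
    """Drop genes with zero total expression; log2(x+1)-transform raw counts."""

    def _one(df: pd.DataFrame) -> pd.DataFrame:
        if counts_are_raw and (df.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        expressed = df.sum(axis=1) > 0
        n_dropped = int((~expressed).sum())
        if n_dropped:
            logger.info("preprocess: removed %d unexpressed genes", n_dropped)
        out = df.loc[expressed]
        if counts_are_raw:
            out = np.log2(out + 1.0)
        return out

    return ExpressionBundle(
        lnc_expr=_one(bundle.lnc_expr),
        mrna_expr=_one(bundle.mrna_expr),
        purity=bundle.purity,
    )


def read_gmt(path: str | Path, universe_size: int | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    logger.warning("read_gmt: duplicate gene %r in set %r", g, name)
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: GMT file contains no gene sets")
    coll = GeneSetCollection(sets=sets)
    if universe_size is not None:
        coll.universe_size = universe_size
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    return validate_survival(pd.read_csv(path, sep="\t"))


def write_survival(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index() if table.index.name == "sample_id" else table
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_bundle(bundle: ExpressionBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as expression/annotation/purity TSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "annotation": directory / "annotation.tsv",
        "purity": directory / "purity.tsv",
    }
    expr = pd.concat([bundle.lnc_expr, bundle.mrna_expr])
    write_matrix(expr, paths["expression"])
    ann = pd.DataFrame(
        {
            "gene_id": list(bundle.lnc_expr.index) + list(bundle.mrna_expr.index),
            "biotype": ["lncRNA"] * len(bundle.lnc_expr) + ["mRNA"] * len(bundle.mrna_expr),
        }
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    bundle.purity.rename("purity").to_csv(
        paths["purity"], sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT
    )
    return paths


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run discovery -> association -> subtyping -> scoring -> prognosis.

    The config file declares input paths (``expression``, ``annotation``,
    ``purity``, ``pathways_gmt``, ``markers_gmt``, ``survival``), an output
    directory (``out_dir``, overridable by argument) and thresholds
    (see :data:`DEFAULT_CONFIG`).  Identical config + seed gives
    byte-identical output tables.
    """
    from . import cellassoc, lncres, prognosis, subtyping

    cfg = load_config(config_path)
    for key in ("expression", "annotation", "purity", "pathways_gmt", "markers_gmt", "survival"):
        if key not in cfg:
            raise ValueError(f"config missing required input path {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found: {cfg[key]}")
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "immlnc_out"))
    out.mkdir(parents=True, exist_ok=True)

    run_log: dict = {"config": {k: str(v) for k, v in cfg.items()}, "stages": {}}

    bundle = read_expression(cfg["expression"], cfg["annotation"], cfg["purity"])
    bundle = preprocess(bundle, counts_are_raw=bool(cfg["counts_are_raw"]))
    pathways = read_gmt(cfg["pathways_gmt"])
    markers = read_gmt(cfg["markers_gmt"])
    survival = read_survival(cfg["survival"])
    survival = survival.loc[survival.index.intersection(bundle.sample_ids)]

    # --- stage 1: purity-adjusted correlation + enrichment screen -----------
    logger.info("lncres: threshold=%s two_sided=%s", cfg["lncres_threshold"], cfg["lncres_two_sided"])
    corr = lncres.correlation_stats(bundle, adjust_purity=bool(cfg["adjust_purity"]))
    enr = lncres.score_lncres(corr, pathways, weight_exponent=float(cfg["weight_exponent"]))
    immune_lncs = lncres.screen_immune_lncrnas(
        enr, threshold=float(cfg["lncres_threshold"]), two_sided=bool(cfg["lncres_two_sided"])
    )
    enr_out = enr.copy()
    enr_out["passed"] = _passes_screen(enr_out, cfg)
    enr_out.to_csv(out / "lncres.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    _write_ids(sorted(immune_lncs), out / "immune_lncrnas.txt")
    run_log["stages"]["lncres"] = {"n_immune_lncrnas": len(immune_lncs)}

    # --- stage 2: hypergeometric immune-cell association --------------------
    logger.info("associate: p<%s, k>=%s", cfg["hyper_p"], cfg["min_overlap"])
    assoc, disorder_lncs = cellassoc.associate_cells(
        sorted(immune_lncs),
        corr,
        markers,
        alpha=float(cfg["corr_alpha"]),
        use_fdr=bool(cfg["corr_use_fdr"]),
        p_thresh=float(cfg["hyper_p"]),
        min_overlap=int(cfg["min_overlap"]),
        restrict_to_universe=bool(cfg["restrict_to_universe"]),
    )
    candidates = cellassoc.intersect_candidates(immune_lncs, disorder_lncs)
    assoc.to_csv(out / "cell_association.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    _write_ids(candidates, out / "candidate_lncrnas.txt")
    run_log["stages"]["associate"] = {
        "n_disorder_lncrnas": len(disorder_lncs),
        "n_candidates": len(candidates),
    }
    if len(candidates) < 2:
        _finish(run_log, out, status="partial: fewer than 2 candidate lncRNAs")
        raise RuntimeError("fewer than 2 candidate lncRNAs; cannot cluster")

    # --- stage 3: consensus clustering of samples ----------------------------
    k_range = range(int(cfg["k_min"]), int(cfg["k_max"]) + 1)
    logger.info("cluster: k=%s..%s resamples=%s", cfg["k_min"], cfg["k_max"], cfg["n_resamples"])
    cons = subtyping.consensus_cluster(
        bundle.lnc_expr.loc[candidates],
        k_range=k_range,
        n_resamples=int(cfg["n_resamples"]),
        subsample_frac=float(cfg["subsample_frac"]),
        seed=int(cfg["seed"]),
    )
    labels = pd.Series(cons.labels[cons.k_opt], index=bundle.sample_ids, name="subtype")
    labels.to_csv(out / "subtypes.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        {"k": list(cons.stability.keys()), "pac": list(cons.stability.values())}
    ).to_csv(out / "consensus_stability.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    run_log["stages"]["cluster"] = {"k_opt": int(cons.k_opt)}

    # --- stage 4: per-sample ssGSEA scores -----------------------------------
    scores = subtyping.score_all(bundle.mrna_expr, markers, alpha=float(cfg["ssgsea_alpha"]))
    scores.to_csv(out / "ssgsea_cells.tsv", sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)

    # --- stage 5: pick the two prognostically most distinct subtypes ---------
    g_a, g_b = _most_distinct_pair(labels, survival)
    run_log["stages"]["de_groups"] = {"group_a": int(g_a), "group_b": int(g_b)}
    sel = labels[labels.isin([g_a, g_b])]
    logger.info("de_screen: p<%s |log2FC|>%s between subtypes %s and %s",
                cfg["de_p"], cfg["de_lfc"], g_a, g_b)
    de = subtyping.de_screen(
        bundle.mrna_expr[sel.index],
        (sel == g_a),
        p_thresh=float(cfg["de_p"]),
        lfc_thresh=float(cfg["de_lfc"]),
    )
    de.to_csv(out / "de_genes.tsv", sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)
    degs = list(de.index[de["passed"]])
    run_log["stages"]["de"] = {"n_degs": len(degs)}

    # --- stage 6: prognostic risk model --------------------------------------
    surv_expr = bundle.mrna_expr[survival.index]
    logger.info("prognosis: univariate p<%s", cfg["cox_p"])
    uni = prognosis.univariate_cox_screen(surv_expr.loc[degs], survival, p_thresh=float(cfg["cox_p"]))
    uni.to_csv(out / "univariate_cox.tsv", sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)
    panel = list(uni.index[uni["passed"]])
    max_panel = max(2, len(survival) // 5)
    if len(panel) > max_panel:
        panel = list(uni.loc[panel].sort_values("pval").index[:max_panel])
    if len(panel) < 1:
        _finish(run_log, out, status="partial: no prognostic genes passed the screen")
        raise RuntimeError("no prognostic genes passed the univariate screen")
    model = prognosis.fit_risk_model(
        surv_expr, survival, panel, score_mode=str(cfg["score_mode"])
    )
    (out / "risk_model.json").write_text(model.to_json())
    scores_s = prognosis.risk_score(model, surv_expr)
    strata = prognosis.stratify_median(scores_s)
    strata.to_csv(out / "risk_scores.tsv", sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)
    _, chi2, logrank_p = prognosis.km_logrank(strata, survival)
    aucs = prognosis.time_dependent_auc(
        scores_s, survival, horizons=list(cfg["auc_horizons"])
    )
    pd.Series(aucs, name="auc").to_csv(
        out / "time_auc.tsv", sep="\t", index_label="horizon_days", float_format=FLOAT_FORMAT
    )
    run_log["stages"]["prognosis"] = {
        "panel_size": len(model.genes),
        "logrank_chi2": float(chi2),
        "logrank_p": float(logrank_p),
        "auc": {str(k): float(v) for k, v in aucs.items()},
    }

    _finish(run_log, out, status="ok")
    return out


def _passes_screen(enr: pd.DataFrame, cfg: Mapping) -> pd.Series:
    thr = float(cfg["lncres_threshold"])
    if cfg["lncres_two_sided"]:
        return enr["lncres"].abs() > thr
    return enr["lncres"] > thr


def _most_distinct_pair(labels: pd.Series, survival: pd.DataFrame) -> tuple[int, int]:
    """Pair of subtypes with the smallest pairwise log-rank p (needs >=3 each)."""
    from itertools import combinations

    from lifelines.statistics import logrank_test

    shared = labels.index.intersection(survival.index)
    labels = labels.loc[shared]
    best, best_p = None, np.inf
    for a, b in combinations(sorted(labels.unique()), 2):
        ia, ib = labels.index[labels == a], labels.index[labels == b]
        if len(ia) < 3 or len(ib) < 3:
            continue
        res = logrank_test(
            survival.loc[ia, "time"], survival.loc[ib, "time"],
            event_observed_A=survival.loc[ia, "event"],
            event_observed_B=survival.loc[ib, "event"],
        )
        if res.p_value < best_p:
            best, best_p = (int(a), int(b)), res.p_value
    if best is None:
        raise RuntimeError("no subtype pair with at least 3 samples each")
    return best


def _write_ids(ids: Iterable[str], path: Path) -> None:
    path.write_text("".join(f"{i}\n" for i in ids))


def _finish(run_log: dict, out: Path, status: str) -> None:
    run_log["status"] = status
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
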