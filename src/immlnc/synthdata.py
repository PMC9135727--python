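"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a bulk tumor RNA-seq cohort in which immune signal is
confounded by tumor purity: every immune pathway has a latent per-sample
activity that rises as purity falls (immune cells occupy the non-tumor
fraction of the biopsy).  Three lncRNA classes are implanted:

* **drivers** — coupled to a pathway's latent activity itself, so their
  association with pathway genes survives adjustment for purity;
* **confounded** — coupled only to (1 - purity), so their marginal
  correlation with immune genes is entirely explained by purity and
  vanishes under partial correlation;
* **null** — independent noise.

Ground truth (which lncRNA is which, subtype labels, true Cox coefficients)
is returned alongside the data so recovery can be measured.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .iodata import (
    ExpressionBundle,
    GeneSetCollection,
    validate_survival,
    write_bundle,
    write_gmt,
    write_survival,
)

# Latent-structure constants (log2 scale).  Each pathway's activity factor
# correlates with standardized (1 - purity) with a pathway-specific rho
# spread over [RHO_MIN, RHO_MAX]: some immune populations track overall
# infiltration tightly, others only loosely.  Within a pathway a minority of
# genes are core members with a strong factor loading; the rest are
# peripheral with a weak loading, as in real expression programs.
RHO_MAX = 0.75
RHO_MIN = 0.35
NOISE_SD = 1.0
LOADING_STRONG = 1.0
LOADING_WEAK = 0.15
STRONG_FRAC = 0.2
LNC_NOISE_SD = 0.8
DEFAULT_PATHWAY_SIZE = 120
BASELINE_MEAN = 6.0
BASELINE_SD = 1.0
#: additive shift applied to a subset of driver lncRNAs per subtype
SUBTYPE_SHIFT = 2.2
#: per-subtype mRNA program: block size and log2 shift (drives the DE screen)
SUBTYPE_MRNA_BLOCK = 30
SUBTYPE_MRNA_SHIFT = 1.5
#: marker universe target: total distinct marker genes across the 24 cell sets
MARKER_UNIVERSE = 2025
#: baseline time scale of the exponential survival model, days
BASELINE_SCALE_DAYS = 1500.0


@dataclass
class SimulationTruth:
    """Ground-truth labels of a simulated cohort."""

    driver_lncs: dict[str, float]        # lnc id -> coupling gamma
    driver_pathway: dict[str, str]       # lnc id -> pathway it follows
    confounded_lncs: dict[str, float]    # lnc id -> purity coupling delta
    null_lncs: list[str]
    subtype_labels: dict[str, int]       # sample id -> 1..K_true
    risk_genes: dict[str, float]         # gene id -> true Cox coefficient

    def __post_init__(self) -> None:
        d, c, n = set(self.driver_lncs), set(self.confounded_lncs), set(self.null_lncs)
        if d & c or d & n or c & n:
            raise ValueError("driver / confounded / null lncRNA sets must be disjoint")
        if len(set(self.subtype_labels.values())) < 2:
            raise ValueError("K_true must be at least 2")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))


@dataclass
class SimulatedCohort:
    bundle: ExpressionBundle
    pathways: GeneSetCollection
    markers: GeneSetCollection
    survival: pd.DataFrame
    truth: SimulationTruth
    #: pathway -> correlation of its activity factor with (1 - purity)
    purity_coupling: dict[str, float] | None = None
    #: pathway -> its strongly loaded ("core") genes
    strong_genes: dict[str, list[str]] | None = None
    #: latent per-sample pathway activities (pathway x sample), for checking
    #: that implanted couplings are recovered
    activity: pd.DataFrame | None = None


def simulate(
    n_samples: int = 200,
    n_mrna: int = 2000,
    n_lnc: int = 500,
    n_pathways: int = 10,
    n_cell_types: int = 24,
    n_drivers: int = 15,
    n_confounded: int = 15,
    gamma: float = 1.0,
    delta: float = 2.0,
    K_true: int = 4,
    beta_scale: float = 1.0,
    n_risk_genes: int = 5,
    censor_frac: float = 0.4,
    pathway_size: int | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Generate one cohort; identical arguments and seed give identical output.

    Parameters follow the model in the module docstring.  ``gamma`` and
    ``delta`` are couplings on the standardized latent scale, so the
    population correlation between a driver lncRNA and its pathway factor is
    gamma / sqrt(gamma^2 + sigma^2).
    """
    for name, v in {
        "n_samples": n_samples, "n_mrna": n_mrna, "n_lnc": n_lnc,
        "n_pathways": n_pathways, "n_cell_types": n_cell_types, "K_true": K_true,
    }.items():
        if v < 2:
            raise ValueError(f"{name} must be >= 2 (got {v})")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must lie in [0, 1)")
    if gamma == 0 and delta == 0:
        warnings.warn("gamma=delta=0: no implanted signal; recovery tests will fail")

    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    mrnas = [f"G{i:05d}" for i in range(n_mrna)]
    lncs = [f"L{i:04d}" for i in range(n_lnc)]

    # purity and the shared immune axis -------------------------------------
    purity = rng.beta(5.0, 2.0, size=n_samples)
    z = 1.0 - purity
    z = (z - z.mean()) / z.std()

    # one latent activity per pathway, correlated with (1 - purity) with a
    # pathway-specific strength
    rho = np.linspace(RHO_MAX, RHO_MIN, num=n_pathways)
    activity = rho[:, None] * z[None, :] + np.sqrt(1 - rho**2)[:, None] * rng.normal(
        size=(n_pathways, n_samples)
    )

    # mRNAs: pathway blocks then background ----------------------------------
    if pathway_size is None:
        pathway_size = DEFAULT_PATHWAY_SIZE
    pathway_size = min(pathway_size, n_mrna // n_pathways)
    pathway_names = [f"PATH{k:02d}" for k in range(n_pathways)]
    pathway_sets: dict[str, list[str]] = {}
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_mrna)
    mrna = baseline[:, None] + rng.normal(scale=NOISE_SD, size=(n_mrna, n_samples))
    n_strong = max(1, int(round(STRONG_FRAC * pathway_size)))
    strong_genes: dict[str, list[str]] = {}
    for k in range(n_pathways):
        lo = k * pathway_size
        loadings = np.full(pathway_size, LOADING_WEAK)
        loadings[:n_strong] = LOADING_STRONG
        mrna[lo : lo + pathway_size] += loadings[:, None] * activity[k][None, :]
        pathway_sets[pathway_names[k]] = mrnas[lo : lo + pathway_size]
        strong_genes[pathway_names[k]] = mrnas[lo : lo + n_strong]
    n_pathway_genes = n_pathways * pathway_size
    background = mrnas[n_pathway_genes:]

    # marker gene sets: every universe gene belongs to >= 1 cell type ---------
    universe_n = min(MARKER_UNIVERSE, n_mrna)
    universe = mrnas[:n_pathway_genes] + background[: universe_n - n_pathway_genes]
    cell_names = [f"CELL{c:02d}" for c in range(n_cell_types)]
    marker_sets: dict[str, set[str]] = {c: set() for c in cell_names}
    # cell types of a pathway share its core genes (related populations use
    # the same canonical markers); peripheral genes are split round-robin
    for k in range(n_pathways):
        cells_k = [c for c in range(n_cell_types) if c % n_pathways == k]
        core = set(strong_genes[pathway_names[k]])
        for c in cells_k:
            marker_sets[cell_names[c]].update(core)
        peripheral = [g for g in pathway_sets[pathway_names[k]] if g not in core]
        for i, g in enumerate(peripheral):
            marker_sets[cell_names[cells_k[i % len(cells_k)]]].add(g)
    for i, g in enumerate(universe[n_pathway_genes:]):
        marker_sets[cell_names[i % n_cell_types]].add(g)
    # small cross-pathway overlap so marker sets are not a clean partition
    for c in cell_names:
        marker_sets[c].update(rng.choice(universe, size=5, replace=False))
    markers = GeneSetCollection(
        sets={c: sorted(marker_sets[c]) for c in cell_names},
    )

    # lncRNAs -----------------------------------------------------------------
    if n_drivers + n_confounded > n_lnc:
        # small cohorts: keep the three classes in roughly default proportion
        n_drivers = max(1, n_lnc // 3)
        n_confounded = max(1, n_lnc // 3)
    driver_ids = lncs[:n_drivers]
    confounded_ids = lncs[n_drivers : n_drivers + n_confounded]
    null_ids = lncs[n_drivers + n_confounded :]

    subtype = rng.integers(1, K_true + 1, size=n_samples)

    # each subtype up-regulates its own block of background mRNAs (the
    # expression programs the between-subtype DE screen is meant to find)
    block = min(SUBTYPE_MRNA_BLOCK, max(1, (n_mrna - n_pathway_genes) // max(K_true, 1)))
    subtype_block_genes: list[str] = []
    for s in range(K_true):
        rows = [n_mrna - (s + 1) * block + i for i in range(block)]
        mrna[rows] += SUBTYPE_MRNA_SHIFT * (subtype == s + 1)[None, :]
        subtype_block_genes.extend(mrnas[r] for r in rows)
    lnc = rng.normal(scale=LNC_NOISE_SD, size=(n_lnc, n_samples))
    driver_pathway: dict[str, str] = {}
    for d, lid in enumerate(driver_ids):
        k = d % n_pathways
        driver_pathway[lid] = pathway_names[k]
        lnc[d] += gamma * activity[k]
        # subtype structure: driver d is shifted up in subtype (d mod K) + 1
        lnc[d] += SUBTYPE_SHIFT * (subtype == (d % K_true) + 1)
    for j, lid in enumerate(confounded_ids):
        lnc[n_drivers + j] += delta * z
    lnc += BASELINE_MEAN  # common log2 baseline; irrelevant to correlations

    # survival: hazard is driven by genes inside the subtype programs, so the
    # DEG-based prognostic route of the analysis has true signal to recover
    risk_gene_ids = subtype_block_genes[:: max(1, len(subtype_block_genes) // n_risk_genes)][:n_risk_genes]
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(risk_gene_ids))])
    betas = beta_scale * signs * np.linspace(1.0, 0.6, num=len(risk_gene_ids))
    risk_rows = [mrnas.index(g) for g in risk_gene_ids]
    lp = betas @ (mrna[risk_rows] - mrna[risk_rows].mean(axis=1, keepdims=True))
    times = rng.exponential(scale=BASELINE_SCALE_DAYS * np.exp(-lp))
    times = np.maximum(times, 1.0)
    event = np.ones(n_samples, dtype=int)
    n_censor = int(round(censor_frac * n_samples))
    if n_censor:
        idx = rng.choice(n_samples, size=n_censor, replace=False)
        times[idx] *= rng.uniform(0.05, 0.95, size=n_censor)
        event[idx] = 0

    bundle = ExpressionBundle(
        lnc_expr=pd.DataFrame(lnc, index=lncs, columns=samples),
        mrna_expr=pd.DataFrame(mrna, index=mrnas, columns=samples),
        purity=pd.Series(purity, index=samples, name="purity"),
    )
    survival = validate_survival(
        pd.DataFrame({"sample_id": samples, "time": times, "event": event})
    )
    truth = SimulationTruth(
        driver_lncs={lid: gamma for lid in driver_ids},
        driver_pathway=driver_pathway,
        confounded_lncs={lid: delta for lid in confounded_ids},
        null_lncs=list(null_ids),
        subtype_labels={s: int(k) for s, k in zip(samples, subtype)},
        risk_genes={g: float(b) for g, b in zip(risk_gene_ids, betas)},
    )
    return SimulatedCohort(
        bundle=bundle,
        pathways=GeneSetCollection(sets=pathway_sets, universe_size=n_mrna),
        markers=markers,
        survival=survival,
        truth=truth,
        purity_coupling={pathway_names[k]: float(rho[k]) for k in range(n_pathways)},
        strong_genes=strong_genes,
        activity=pd.DataFrame(activity, index=pathway_names, columns=samples),
    )


def write_fixture(cohort: SimulatedCohort, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write every input of the pipeline plus the truth JSON to ``directory``."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_bundle(cohort.bundle, directory)
    paths["pathways_gmt"] = directory / "pathways.gmt"
    write_gmt(cohort.pathways, paths["pathways_gmt"])
    paths["markers_gmt"] = directory / "markers.gmt"
    write_gmt(cohort.markers, paths["markers_gmt"])
    paths["survival"] = directory / "survival.tsv"
    write_survival(cohort.survival, paths["survival"])
    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(cohort.truth.to_json())
    return paths
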