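"""Synthetic cohorts with planted ground truth.

Two generators mirror the real study designs the pipeline targets:

* :func:`simulate_expression_cohort` — a log2 gene-expression cohort with two
  pathway-gene cores (alanine-aspartate-glutamate and glycolysis/
  gluconeogenesis style), four planted metabolic subtypes (quiescent / AAG /
  GG / mixed) defined by which cores are "on", and subtype-dependent
  exponential survival.
* :func:`simulate_metabolome_cohort` — a two-arm (tumour vs healthy) serum
  metabolome with log-normal intensities, planted fold changes, block-
  correlated metabolite modules, and one module tied to an ordinal HER2 IHC
  trait.

Every generator is deterministic under its seed, and returns a ``SimTruth``
record naming the planted structure for parameter-recovery tests.

Core-gene correlation model: the covariance between two core genes is split
into an activity component (the shared on/off shift), a shared latent factor,
and independent noise, with the weights solved so the marginal pairwise
correlation equals the configured target exactly in expectation.  At
activity_shift = 0 this reduces to the pure latent-factor construction
x = sqrt(rho)*f + sqrt(1-rho)*eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection, MetaboliteAbundanceMatrix

__all__ = [
    "SubtypeSimConfig",
    "MetabolomeSimConfig",
    "ModuleSpec",
    "DemSpec",
    "SimTruth",
    "simulate_expression_cohort",
    "simulate_metabolome_cohort",
    "make_gene_sets",
]

SUBTYPES = ("quiescent", "AAG", "GG", "mixed")


@dataclass
class SubtypeSimConfig:
    n_samples: int = 400
    n_background_genes: int = 800
    core_size: int = 20
    decoy_size: int = 15
    within_core_correlation: float = 0.8
    subtype_proportions: dict = field(
        default_factory=lambda: {"quiescent": 0.25, "AAG": 0.25, "GG": 0.25, "mixed": 0.25}
    )
    activity_shift: float = 1.5  # sd units added to core genes when the pathway is on
    noise_sd: float = 1.0
    latent_weight: float = 0.3  # share of residual core covariance carried by a latent factor
    baseline_hazard: float = np.log(2) / 730.0  # per day; median survival 2 years
    log_hazard_ratios: dict = field(
        default_factory=lambda: {"quiescent": 0.0, "AAG": 0.0, "GG": np.log(2.0), "mixed": np.log(0.5)}
    )
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.subtype_proportions
        if set(props) != set(SUBTYPES):
            raise ValueError(f"subtype_proportions must cover {SUBTYPES}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if not (0.0 <= self.within_core_correlation < 1.0):
            raise ValueError("within_core_correlation must be in [0, 1)")
        if self.activity_shift < 0:
            raise ValueError("activity_shift must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class ModuleSpec:
    size: int
    within_correlation: float
    trait_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_correlation < 1.0):
            raise ValueError("within_correlation must be in (0,1)")
        if not (-1.0 < self.trait_correlation < 1.0):
            raise ValueError("trait_correlation must be in (-1,1)")
        if self.size < 2:
            raise ValueError("module size must be >= 2")


@dataclass
class DemSpec:
    n_up: int = 50
    fc_up: float = 1.5
    n_down: int = 100
    fc_down: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ValueError("fold changes must be > 0")


@dataclass
class MetabolomeSimConfig:
    n_gc: int = 112
    n_healthy: int = 112
    n_metabolites: int = 1300
    module_spec: list = field(
        default_factory=lambda: [
            ModuleSpec(20, 0.7, 0.5),
            ModuleSpec(20, 0.7, 0.0),
            ModuleSpec(15, 0.8, 0.0),
        ]
    )
    dem_spec: DemSpec | None = field(default_factory=DemSpec)
    lognormal_sigma: float = 0.3  # sd of natural-log intensities
    her2_distribution: tuple = (0.4, 0.25, 0.2, 0.15)  # P(IHC = 0..3) among tumour samples
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.her2_distribution) - 1.0) > 1e-9:
            raise ValueError("her2_distribution must sum to 1")
        n_module = sum(m.size for m in self.module_spec)
        if n_module > self.n_metabolites:
            raise ValueError("module sizes exceed n_metabolites")
        n_dem = 0 if self.dem_spec is None else self.dem_spec.n_up + self.dem_spec.n_down
        if n_module + n_dem > self.n_metabolites:
            raise ValueError("modules + planted DEMs exceed n_metabolites")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")


@dataclass
class SimTruth:
    true_subtype: dict | None = None          # sample -> subtype label
    true_cores: dict | None = None            # pathway -> core gene ids
    true_modules: dict | None = None          # metabolite -> module index
    true_dems: dict | None = None             # metabolite -> "up" | "down"
    trait_module: int | None = None           # index of the HER2-linked module


def _core_weights(rho: float, shift: float, p_on: float, latent_weight: float) -> tuple[float, float, float]:
    """Solve (shift, latent, noise) weights so marginal pairwise corr = rho.

    cov = s2 + b2, var = s2 + b2 + c2 with s2 = shift^2 * p(1-p); b2 takes a
    configurable share of whatever covariance the activity does not supply.
    """
    s2 = shift**2 * p_on * (1.0 - p_on)
    if rho == 0.0:
        return shift, 0.0, 1.0
    b2 = latent_weight * max(0.0, rho - s2)
    v = (s2 + b2) / rho
    c2 = v - s2 - b2
    if v <= 0 or c2 < 0:  # activity alone over-delivers; pad with noise only
        c2 = s2 * (1.0 - rho) / rho
    return shift, float(np.sqrt(b2)), float(np.sqrt(max(c2, 1e-12)))


def _censoring_horizon(hazards: np.ndarray, rate: float) -> float:
    """Uniform(0, m) censoring horizon giving the target expected censoring rate."""

    def mean_cens(m: float) -> float:
        lm = hazards * m
        return float(np.mean((1.0 - np.exp(-lm)) / lm)) - rate

    lo, hi = 1e-6, 1e6 / hazards.mean()
    return brentq(mean_cens, lo, hi, xtol=1e-9)


def simulate_expression_cohort(
    cfg: SubtypeSimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Simulate a log2 expression cohort with four planted metabolic subtypes."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    props = np.array([cfg.subtype_proportions[s] for s in SUBTYPES])
    subtype = rng.choice(len(SUBTYPES), size=n, p=props)
    subtype_labels = np.array(SUBTYPES)[subtype]

    pathways = {
        "AAG": np.isin(subtype_labels, ["AAG", "mixed"]).astype(float),
        "GG": np.isin(subtype_labels, ["GG", "mixed"]).astype(float),
    }

    gene_blocks = []
    gene_ids: list[str] = []
    true_cores: dict[str, list[str]] = {}
    for pw, on in pathways.items():
        p_on = float(np.array([cfg.subtype_proportions[s] for s in SUBTYPES if s in (pw, "mixed")]).sum())
        a, b, c = _core_weights(cfg.within_core_correlation, cfg.activity_shift, p_on, cfg.latent_weight)
        f = rng.standard_normal(n)
        core_ids = [f"{pw}_core_{i:03d}" for i in range(1, cfg.core_size + 1)]
        eps = rng.standard_normal((cfg.core_size, n))
        block = cfg.noise_sd * (a * on[None, :] + b * f[None, :] + c * eps)
        gene_blocks.append(block)
        gene_ids.extend(core_ids)
        true_cores[pw] = core_ids
        decoy_ids = [f"{pw}_decoy_{i:03d}" for i in range(1, cfg.decoy_size + 1)]
        gene_blocks.append(cfg.noise_sd * rng.standard_normal((cfg.decoy_size, n)))
        gene_ids.extend(decoy_ids)

    bg_ids = [f"g{i:05d}" for i in range(1, cfg.n_background_genes + 1)]
    gene_blocks.append(cfg.noise_sd * rng.standard_normal((cfg.n_background_genes, n)))
    gene_ids.extend(bg_ids)

    values = np.vstack(gene_blocks)
    baseline = rng.uniform(4.0, 12.0, size=values.shape[0])
    values = values + baseline[:, None]
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))

    hazards = cfg.baseline_hazard * np.exp(
        np.array([cfg.log_hazard_ratios[s] for s in subtype_labels])
    )
    t_true = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        horizon = _censoring_horizon(hazards, cfg.censoring_rate)
        c_times = rng.uniform(0.0, horizon, size=n)
        os_time = np.minimum(t_true, c_times)
        os_event = (t_true <= c_times).astype(int)
    else:
        os_time, os_event = t_true, np.ones(n, dtype=int)
    # disease-specific survival: a death is disease-related with prob 0.9
    disease_death = rng.random(n) < 0.9
    dss_event = os_event * disease_death.astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": "GC",
                "os_time": np.round(os_time, 1),
                "os_event": os_event,
                "dss_time": np.round(os_time, 1),
                "dss_event": dss_event,
                "stage": rng.choice(["I", "II", "III", "IV"], size=n),
                "grade": rng.choice(["G1", "G2", "G3"], size=n),
                "her2_ihc": np.nan,
                "immune_subtype": rng.choice([f"C{i}" for i in range(1, 7)], size=n),
            }
        )
    )
    truth = SimTruth(
        true_subtype=dict(zip(samples, subtype_labels)),
        true_cores=true_cores,
    )
    return expr, clinical, truth


def simulate_metabolome_cohort(
    cfg: MetabolomeSimConfig,
) -> tuple[MetaboliteAbundanceMatrix, ClinicalTable, SimTruth]:
    """Simulate a two-arm log-normal serum metabolome with planted structure.

    Planted fold changes are exact arithmetic-mean ratios (the group shift is
    applied on the natural-log scale with equal variances, so the log-normal
    mean ratio equals the configured fold change).  Trait-linked modules share
    a latent factor partially aligned with the standardized HER2 IHC score of
    the tumour arm.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_gc + cfg.n_healthy
    samples = [f"GC{i:04d}" for i in range(1, cfg.n_gc + 1)] + [
        f"HC{i:04d}" for i in range(1, cfg.n_healthy + 1)
    ]
    is_gc = np.array([1] * cfg.n_gc + [0] * cfg.n_healthy, dtype=bool)
    groups = np.where(is_gc, "GC", "healthy")

    her2 = np.full(n, np.nan)
    if cfg.n_gc > 0:
        her2[is_gc] = rng.choice(4, size=cfg.n_gc, p=np.asarray(cfg.her2_distribution))

    sigma = cfg.lognormal_sigma
    log_x = np.empty((cfg.n_metabolites, n))
    met_ids = [f"m{i:05d}" for i in range(1, cfg.n_metabolites + 1)]

    true_modules: dict[str, int] = {}
    trait_module: int | None = None
    row = 0
    for j, mod in enumerate(cfg.module_spec):
        f = rng.standard_normal(n)
        if mod.trait_correlation != 0.0 and cfg.n_gc > 1:
            tau = mod.trait_correlation / np.sqrt(mod.within_correlation)
            if abs(tau) >= 1.0:
                raise ValueError(
                    "trait_correlation must not exceed sqrt(within_correlation)"
                )
            h = her2[is_gc]
            h_std = (h - h.mean()) / h.std()
            f_gc = tau * h_std + np.sqrt(1.0 - tau**2) * rng.standard_normal(cfg.n_gc)
            f[is_gc] = f_gc
            trait_module = j
        rho = mod.within_correlation
        eps = rng.standard_normal((mod.size, n))
        block = sigma * (np.sqrt(rho) * f[None, :] + np.sqrt(1.0 - rho) * eps)
        log_x[row : row + mod.size] = block
        for m in met_ids[row : row + mod.size]:
            true_modules[m] = j
        row += mod.size

    n_rest = cfg.n_metabolites - row
    log_x[row:] = sigma * rng.standard_normal((n_rest, n))

    true_dems: dict[str, str] = {}
    if cfg.dem_spec is not None and (cfg.dem_spec.n_up or cfg.dem_spec.n_down):
        ds = cfg.dem_spec
        up_rows = range(row, row + ds.n_up)
        down_rows = range(row + ds.n_up, row + ds.n_up + ds.n_down)
        for r in up_rows:
            log_x[r, is_gc] += np.log(ds.fc_up)
            true_dems[met_ids[r]] = "up"
        for r in down_rows:
            log_x[r, is_gc] += np.log(ds.fc_down)
            true_dems[met_ids[r]] = "down"

    baseline = rng.uniform(np.log(1e4), np.log(1e7), size=cfg.n_metabolites)
    intensities = np.exp(baseline[:, None] + log_x)
    matrix = MetaboliteAbundanceMatrix(
        pd.DataFrame(intensities, index=met_ids, columns=samples),
        group=pd.Series(groups, index=samples),
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": groups,
                "her2_ihc": her2,
                "stage": np.where(is_gc, rng.choice(["I", "II", "III", "IV"], size=n), None),
                "grade": np.where(is_gc, rng.choice(["G1", "G2", "G3"], size=n), None),
            }
        )
    )
    truth = SimTruth(true_modules=true_modules, true_dems=true_dems, trait_module=trait_module)
    return matrix, clinical, truth


def make_gene_sets(
    cfg: SubtypeSimConfig, n_immune_sets: int = 29, immune_set_size: int = 25
) -> GeneSetCollection:
    """Gene-set fixture matching :func:`simulate_expression_cohort` ids.

    Emits one AAG-like and one GG-like pathway set (core plus decoy genes) and
    ``n_immune_sets`` pairwise-disjoint random background-gene sets standing in
    for immune signatures.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    needed = n_immune_sets * immune_set_size
    if needed > cfg.n_background_genes:
        raise ValueError(
            f"{n_immune_sets} sets of {immune_set_size} need {needed} genes; "
            f"only {cfg.n_background_genes} background genes available"
        )
    sets: dict[str, list[str]] = {}
    for pw in ("AAG", "GG"):
        sets[f"{pw}_METABOLISM"] = [
            f"{pw}_core_{i:03d}" for i in range(1, cfg.core_size + 1)
        ] + [f"{pw}_decoy_{i:03d}" for i in range(1, cfg.decoy_size + 1)]
    bg = [f"g{i:05d}" for i in range(1, cfg.n_background_genes + 1)]
    picks = rng.permutation(len(bg))[:needed]
    for k in range(n_immune_sets):
        chosen = picks[k * immune_set_size : (k + 1) * immune_set_size]
        sets[f"IMMUNE_SET_{k + 1:02d}"] = [bg[i] for i in sorted(chosen)]
    descriptions = {name: "synthetic fixture set" for name in sets}
    return GeneSetCollection(sets, descriptions)
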