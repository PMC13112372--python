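"""Seeded generators for every input the pipeline consumes.

Four generators emulate the data sources of a typical study design:

* ``simulate_counts`` — a 6-sample (3 vs 3) bulk RNA-seq design with
  negative-binomial counts, per-sample size factors, and a planted,
  severity-coupled inflammatory gene module containing Stat3, Ptx3 and
  the seven surrogate-index marker genes.  A latent per-sample severity
  scales the module effect in case animals, which is what induces the
  hub <-> index correlations downstream.
* ``simulate_regulon_libraries`` — GMT-style TF regulon libraries with
  a planted hub whose targets over-represent a planted DEG query set.
* ``simulate_clinical_cohort`` — a two-group pediatric cohort (SeLECTS
  control vs DRE) with skewed variables log-normal, parameterized by
  (median, IQR) quantile matching to the default baseline characteristics.
* ``simulate_mouse_phenotypes`` — per-animal genotype, hippocampal
  p-STAT3 and three peripheral markers (blood NLR, serum CRP, serum
  IL-6) whose pooled-genotype correlation with p-STAT3 is calibrated to
  a configured coupling.

Every generator is a pure function of its config (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .tf_consensus import RegulonLibrary

__all__ = [
    "DEFAULT_MODULE_GENES",
    "ExpressionSimConfig",
    "ExpressionTruth",
    "simulate_counts",
    "RegulonSimConfig",
    "RegulonTruth",
    "simulate_regulon_libraries",
    "GroupDist",
    "CohortSimConfig",
    "simulate_clinical_cohort",
    "MarkerParams",
    "MouseSimConfig",
    "simulate_mouse_phenotypes",
]

DEFAULT_MODULE_GENES = (
    "Stat3",
    "Ptx3",
    "S100a9",
    "Fcgr3",
    "Csf3r",
    "Lck",
    "Zap70",
    "Itga2b",
    "Gng11",
)

_Z75 = 0.6744897501960817  # standard normal 75th percentile


# ---------------------------------------------------------------------------
# expression counts


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration of the bulk RNA-seq count generator.

    ``module_log2fc`` is the planted case-group log2 effect for module
    genes other than the hub; the hub's effect is derived from the
    configured WT/case VST medians.  ``severity_sd`` is the SD of the
    latent per-case-sample severity multiplier (mean 1) applied to
    module effects on the log2 scale.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    baseline_log2_mean_range: tuple = (3.0, 9.0)
    dispersion: float = 0.05
    module_genes: tuple = DEFAULT_MODULE_GENES
    module_log2fc: float = 2.0
    lymphoid_genes: tuple = ("Lck", "Zap70")
    lymphoid_log2fc_fraction: float = 0.25
    severity_sd: float = 0.15
    stat3_wt_median_vst: float = 10.25
    stat3_case_median_vst: float = 11.21
    module_baseline_min_log2: float = 5.0
    size_factor_log_sd: float = 0.1
    gene_names: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersion must be positive")
        if self.module_log2fc < 0 or self.severity_sd < 0:
            raise ValueError("module_log2fc and severity_sd must be nonnegative")
        if not 0.0 <= self.lymphoid_log2fc_fraction <= 1.0:
            raise ValueError("lymphoid_log2fc_fraction must lie in [0, 1]")
        if self.n_genes < len(self.module_genes):
            raise ValueError("n_genes smaller than the module")
        if self.gene_names is not None:
            missing = set(self.module_genes) - set(self.gene_names)
            if missing:
                raise ValueError(f"module genes missing from gene_names: {sorted(missing)}")
            if len(self.gene_names) != self.n_genes:
                raise ValueError("gene_names length must equal n_genes")


@dataclass
class ExpressionTruth:
    is_differential: pd.Series
    log2fc: pd.Series
    severity: pd.Series
    size_factors: pd.Series


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) counts; near-zero dispersion falls back to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_like = disp < 1e-10
    if np.any(poisson_like):
        out[poisson_like] = rng.poisson(mean[poisson_like])
    nb = ~poisson_like
    if np.any(nb):
        size = 1.0 / disp[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_counts(config: ExpressionSimConfig) -> tuple[CountMatrix, ExpressionTruth]:
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    samples = [f"WT{i + 1}" for i in range(n)] + [f"DS{i + 1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples)

    if config.gene_names is not None:
        genes = list(config.gene_names)
    else:
        n_bg = config.n_genes - len(config.module_genes)
        genes = list(config.module_genes) + [f"Gene{i + 1:05d}" for i in range(n_bg)]
    gene_idx = pd.Index(genes)

    lo, hi = config.baseline_log2_mean_range
    base_log2 = rng.uniform(lo, hi, size=len(genes))
    lfc = np.zeros(len(genes))
    module_set = set(config.module_genes)
    # marker-panel genes are well expressed in brain tissue; floor their
    # baselines so the panel reliably survives low-count filtering
    for i, g in enumerate(genes):
        if g in module_set:
            base_log2[i] = max(base_log2[i], config.module_baseline_min_log2)
    lymphoid = set(config.lymphoid_genes)
    for i, g in enumerate(genes):
        if g in module_set:
            # lymphoid markers rise less than myeloid ones: an elevated
            # neutrophil-to-lymphocyte ratio requires asymmetric activation
            frac = config.lymphoid_log2fc_fraction if g in lymphoid else 1.0
            lfc[i] = config.module_log2fc * frac
    # hub calibration: baseline and effect pinned to the configured VST
    # medians; a zero module effect means a true null (hub included)
    hub_i = genes.index("Stat3") if "Stat3" in module_set and "Stat3" in genes else None
    if hub_i is not None:
        wt_mean = 2.0**config.stat3_wt_median_vst - 1.0
        case_mean = 2.0**config.stat3_case_median_vst - 1.0
        base_log2[hub_i] = math.log2(wt_mean)
        if config.module_log2fc > 0:
            lfc[hub_i] = math.log2(case_mean / wt_mean)
        else:
            lfc[hub_i] = 0.0

    severity = np.ones(2 * n)
    if config.severity_sd > 0:
        severity[n:] = np.clip(rng.normal(1.0, config.severity_sd, size=n), 0.0, None)

    sf = np.exp(rng.normal(0.0, config.size_factor_log_sd, size=2 * n))
    disp = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (len(genes),))

    effect = lfc[:, None] * severity[None, :]
    effect[:, :n] = 0.0  # controls carry no module effect
    mean = 2.0 ** (base_log2[:, None] + effect) * sf[None, :]
    counts = _nb_draw(rng, mean, np.repeat(disp[:, None], 2 * n, axis=1))

    cm = CountMatrix(pd.DataFrame(counts, index=gene_idx, columns=samples), groups)
    truth = ExpressionTruth(
        is_differential=pd.Series(lfc != 0, index=gene_idx),
        log2fc=pd.Series(lfc, index=gene_idx),
        severity=pd.Series(severity, index=samples),
        size_factors=pd.Series(sf, index=samples),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# regulon libraries


@dataclass(frozen=True)
class RegulonSimConfig:
    n_libraries: int = 3
    n_tfs_per_library: int = 50
    targets_per_tf: int = 50
    universe_size: int = 2000
    planted_hub_name: str = "STAT3"
    planted_overlap: int = 30
    n_query: int = 100
    tf_pool_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < self.targets_per_tf:
            raise ValueError("universe smaller than targets_per_tf")
        if self.planted_overlap > self.targets_per_tf:
            raise ValueError("planted_overlap cannot exceed targets_per_tf")
        if self.planted_overlap > self.n_query:
            raise ValueError("planted_overlap cannot exceed the query size")
        if self.n_query > self.universe_size:
            raise ValueError("query larger than universe")
        if self.tf_pool_size < self.n_tfs_per_library:
            raise ValueError("TF name pool smaller than n_tfs_per_library")


@dataclass
class RegulonTruth:
    universe: list
    query_genes: list
    hub: str


def simulate_regulon_libraries(
    config: RegulonSimConfig,
) -> tuple[list[RegulonLibrary], RegulonTruth]:
    """Generate ``n_libraries`` regulon libraries sharing a TF name pool.

    The planted hub appears in every library with ``planted_overlap`` of
    its targets drawn from the planted query (up-regulated DEG) set;
    all other TFs draw targets uniformly from the universe.
    """
    rng = np.random.default_rng(config.seed)
    universe = [f"G{i + 1:05d}" for i in range(config.universe_size)]
    query = list(rng.choice(universe, size=config.n_query, replace=False))
    non_query = sorted(set(universe) - set(query))
    tf_pool = [f"TF{i + 1:04d}" for i in range(config.tf_pool_size)]

    libraries = []
    for li in range(config.n_libraries):
        others = rng.choice(tf_pool, size=config.n_tfs_per_library - 1, replace=False)
        regulons: dict[str, frozenset] = {}
        hub_targets = list(
            rng.choice(query, size=config.planted_overlap, replace=False)
        ) + list(
            rng.choice(
                non_query,
                size=config.targets_per_tf - config.planted_overlap,
                replace=False,
            )
        )
        regulons[config.planted_hub_name] = frozenset(hub_targets)
        for tf in others:
            regulons[str(tf)] = frozenset(
                rng.choice(universe, size=config.targets_per_tf, replace=False)
            )
        libraries.append(
            RegulonLibrary(name=f"library_{li + 1}", regulons=regulons,
                           universe=frozenset(universe))
        )
    return libraries, RegulonTruth(universe=universe, query_genes=query,
                                   hub=config.planted_hub_name.upper())


# ---------------------------------------------------------------------------
# clinical cohort


@dataclass(frozen=True)
class GroupDist:
    """(median, q25, q75) of a strictly positive, log-normal variable."""

    median: float
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if not (0 < self.q25 <= self.median <= self.q75):
            raise ValueError("need 0 < q25 <= median <= q75")

    def lognormal_params(self) -> tuple[float, float]:
        mu = math.log(self.median)
        sigma = (math.log(self.q75) - math.log(self.q25)) / (2.0 * _Z75)
        if sigma <= 0:
            raise ValueError("nonpositive scale from degenerate IQR")
        return mu, sigma


# default baseline characteristics (SeLECTS control group, DRE case group)
_CONTROL_DEFAULTS = {
    "age_onset_years": GroupDist(7.00, 5.00, 9.00),
    "bmi": GroupDist(17.12, 14.93, 21.30),
    "wbc": GroupDist(6.27, 5.76, 7.08),
    "platelets": GroupDist(228.00, 215.50, 248.00),
    "crp": GroupDist(0.06, 0.05, 0.08),
    "nlr": GroupDist(0.99, 0.78, 1.18),
}
_CASE_DEFAULTS = {
    "age_onset_years": GroupDist(1.00, 0.40, 3.00),
    "bmi": GroupDist(15.98, 14.82, 17.12),
    "wbc": GroupDist(6.46, 5.93, 7.73),
    "platelets": GroupDist(243.00, 201.00, 293.00),
    "crp": GroupDist(0.10, 0.08, 0.13),
    "nlr": GroupDist(1.21, 1.00, 1.55),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Two-group pediatric cohort generator.

    Skewed variables are log-normal with (median, IQR) matched by
    quantile matching.  Neutrophil/lymphocyte percentages are derived
    from the log-normal NLR and a latent granulocyte+lymphocyte total
    ~N(granulo_lymph_sum_mean, sd), which reproduces both the NLR
    medians and the printed percentage means.  When
    ``outcome_model_coefficients`` is set, group labels are regenerated
    mechanistically from a logistic model on the pooled z-scored
    markers (for parameter-recovery tests).
    """

    n_control: int = 71
    n_case: int = 69
    control: dict = field(default_factory=lambda: dict(_CONTROL_DEFAULTS))
    case: dict = field(default_factory=lambda: dict(_CASE_DEFAULTS))
    male_prop_control: float = 46 / 71
    male_prop_case: float = 38 / 69
    granulo_lymph_sum_mean: float = 90.0
    granulo_lymph_sum_sd: float = 3.0
    outcome_model_coefficients: dict | None = None
    outcome_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("two groups required: n_control and n_case must be >= 1")
        for p in (self.male_prop_control, self.male_prop_case):
            if not 0.0 <= p <= 1.0:
                raise ValueError("sex proportions must lie in [0, 1]")
        if self.granulo_lymph_sum_sd <= 0:
            raise ValueError("granulo_lymph_sum_sd must be positive")


def _sample_group(
    rng: np.random.Generator,
    n: int,
    dists: dict,
    male_prop: float,
    sum_mean: float,
    sum_sd: float,
    group: str,
) -> pd.DataFrame:
    cols = {}
    for var in ("age_onset_years", "bmi", "wbc", "platelets", "crp", "nlr"):
        mu, sigma = dists[var].lognormal_params()
        cols[var] = rng.lognormal(mu, sigma, size=n)
    total = rng.normal(sum_mean, sum_sd, size=n)
    # keep the percentage split physiological
    total = np.clip(total, 60.0, 98.0)
    nlr = cols.pop("nlr")
    cols["lymphocyte_pct"] = total / (1.0 + nlr)
    cols["neutrophil_pct"] = total * nlr / (1.0 + nlr)
    cols["sex"] = np.where(rng.random(n) < male_prop, "male", "female")
    cols["group"] = group
    return pd.DataFrame(cols)


def simulate_clinical_cohort(config: CohortSimConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    ctrl = _sample_group(
        rng, config.n_control, config.control, config.male_prop_control,
        config.granulo_lymph_sum_mean, config.granulo_lymph_sum_sd, "SeLECTS",
    )
    case = _sample_group(
        rng, config.n_case, config.case, config.male_prop_case,
        config.granulo_lymph_sum_mean, config.granulo_lymph_sum_sd, "DRE",
    )
    df = pd.concat([ctrl, case], ignore_index=True)
    order = [
        "group", "age_onset_years", "sex", "bmi", "wbc",
        "neutrophil_pct", "lymphocyte_pct", "platelets", "crp",
    ]
    df = df[order]

    if config.outcome_model_coefficients:
        from scipy.special import expit

        nlr = df["neutrophil_pct"] / df["lymphocyte_pct"]
        markers = {"nlr": nlr, "sii": df["platelets"] * nlr, "crp": df["crp"]}
        eta = np.full(len(df), config.outcome_intercept, dtype=float)
        for name, beta in config.outcome_model_coefficients.items():
            x = markers[name].to_numpy(dtype=float)
            z = (x - x.mean()) / x.std(ddof=1)
            eta += beta * z
        df["group"] = np.where(rng.random(len(df)) < expit(eta), "DRE", "SeLECTS")
    return df


# ---------------------------------------------------------------------------
# mouse phenotypes


@dataclass(frozen=True)
class MarkerParams:
    wt_mean: float
    wt_sd: float
    mut_mean: float
    mut_sd: float

    def __post_init__(self) -> None:
        if self.wt_sd <= 0 or self.mut_sd <= 0:
            raise ValueError("SDs must be positive")


@dataclass(frozen=True)
class MouseSimConfig:
    """Mouse phenotype generator calibrated to the in-vivo group statistics.

    ``coupling_r`` values are the target pooled-genotype Pearson
    correlations between hippocampal p-STAT3 and each peripheral
    marker; the within-genotype bivariate-normal correlation that
    realizes each pooled target is solved from the configured group
    means/SDs.  CRP and IL-6 are kept nonnegative by rejection sampling.
    """

    n_per_group: int = 24
    nlr: MarkerParams = MarkerParams(0.26, 0.02, 0.54, 0.02)
    crp: MarkerParams = MarkerParams(150.7, 16.4, 339.4, 18.4)  # ng/mL
    il6: MarkerParams = MarkerParams(80.8, 41.5, 206.2, 57.9)  # pg/mL
    pstat3: MarkerParams = MarkerParams(1.0, 0.2, 2.2, 0.2)  # densitometry a.u.
    coupling_r: dict = field(
        default_factory=lambda: {"nlr": 0.96, "crp": 0.94, "il6": 0.74}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for r in self.coupling_r.values():
            if not abs(r) < 1.0:
                raise ValueError("|coupling_r| must be < 1")


def within_group_correlation(
    target_pooled_r: float, marker: MarkerParams, pstat3: MarkerParams
) -> float:
    """Within-genotype correlation yielding a pooled-genotype correlation
    of ``target_pooled_r`` for equal group sizes (population moments)."""
    dx = marker.mut_mean - marker.wt_mean
    dy = pstat3.mut_mean - pstat3.wt_mean
    var_x = (marker.wt_sd**2 + marker.mut_sd**2) / 2.0 + dx**2 / 4.0
    var_y = (pstat3.wt_sd**2 + pstat3.mut_sd**2) / 2.0 + dy**2 / 4.0
    denom = (marker.wt_sd * pstat3.wt_sd + marker.mut_sd * pstat3.mut_sd) / 2.0
    rho = (target_pooled_r * math.sqrt(var_x * var_y) - dx * dy / 4.0) / denom
    if not -1.0 < rho < 1.0:
        raise ValueError(
            f"pooled coupling {target_pooled_r} infeasible for the configured "
            f"group means/SDs (implied within-group correlation {rho:.3f})"
        )
    return rho


def _conditional_marker(
    rng: np.random.Generator, z: np.ndarray, mean: float, sd: float,
    rho: float, nonnegative: bool,
) -> np.ndarray:
    eps = rng.normal(size=z.size)
    val = mean + sd * (rho * z + math.sqrt(1.0 - rho**2) * eps)
    if nonnegative:
        for _ in range(1000):
            bad = val < 0
            if not bad.any():
                break
            eps = rng.normal(size=int(bad.sum()))
            val[bad] = mean + sd * (rho * z[bad] + math.sqrt(1.0 - rho**2) * eps)
        else:
            raise RuntimeError("rejection sampling failed to produce nonnegative values")
    return val


def simulate_mouse_phenotypes(config: MouseSimConfig) -> pd.DataFrame:
    """Per-animal genotype, p-STAT3 and peripheral markers (NLR, CRP, IL-6)."""
    rng = np.random.default_rng(config.seed)
    rho = {
        m: within_group_correlation(config.coupling_r[m], getattr(config, m), config.pstat3)
        for m in ("nlr", "crp", "il6")
    }
    frames = []
    for geno, which in (("WT", "wt"), ("Scn1a+/-", "mut")):
        n = config.n_per_group
        z = rng.normal(size=n)
        pmean = getattr(config.pstat3, f"{which}_mean")
        psd = getattr(config.pstat3, f"{which}_sd")
        row = {"genotype": [geno] * n, "pstat3": pmean + psd * z}
        for m in ("nlr", "crp", "il6"):
            params = getattr(config, m)
            row[m] = _conditional_marker(
                rng, z,
                getattr(params, f"{which}_mean"), getattr(params, f"{which}_sd"),
                rho[m], nonnegative=True,
            )
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)
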