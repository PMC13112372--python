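"""Count-level RNA-seq processing.

Low-count filtering, median-of-ratios size factors, a log2-based
variance-stabilizing normalization, a desk-scale negative-binomial Wald
differential-expression test with Benjamini–Hochberg FDR control, DEG
calling, and PCA of normalized values.

The DE test is intentionally lightweight: per-gene method-of-moments
dispersion (with a global median floor), a Wald statistic on the log2
fold change with a normal reference, and BH adjustment across tested
genes.  It trades the machinery of full NB regression packages for a
transparent estimator whose operating characteristics are validated on
synthetic data with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "DEResult",
    "PCAResult",
    "filter_low_counts",
    "size_factors",
    "vst_normalize",
    "differential_expression",
    "bh_adjust",
    "call_degs",
    "pca",
]

GROUPS = ("control", "case")


@dataclass
class CountMatrix:
    """Raw gene x sample integer counts with a group label per sample.

    ``counts`` is a genes x samples DataFrame (index = gene symbols,
    columns = sample IDs); ``groups`` maps each sample to ``"control"``
    or ``"case"``.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("count matrix is empty")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TypeError("counts must be numeric")
        if np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise ValueError("counts must be nonnegative integers")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class NormalizedMatrix:
    """Gene x sample values on a log2-like VST scale plus the size factors used."""

    values: pd.DataFrame
    size_factors: pd.Series
    groups: pd.Series
    mode: str = "log2p1"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class DEResult:
    """Per-gene differential-expression table, case vs control.

    ``log2fc > 0`` means higher expression in the case group.  Genes with
    zero counts in every sample are excluded from testing (``tested`` is
    False and ``padj`` is NaN for them).
    """

    table: pd.DataFrame
    alpha: float = 0.05
    lfc_cut: float = 0.585

    def up_genes(self) -> list[str]:
        return self.table.index[self.table["is_deg_up"]].tolist()

    def down_genes(self) -> list[str]:
        return self.table.index[self.table["is_deg_down"]].tolist()


@dataclass
class PCAResult:
    scores: pd.DataFrame
    variance_fraction: np.ndarray = field(default_factory=lambda: np.array([]))


def filter_low_counts(
    counts: CountMatrix, min_count: int = 10, max_frac_below: float = 0.5
) -> CountMatrix:
    """Drop genes whose count is below ``min_count`` in more than
    ``max_frac_below`` of samples (strict inequality on the fraction)."""
    frac_below = (counts.counts < min_count).mean(axis=1)
    keep = frac_below <= max_frac_below
    if keep.sum() == 0:
        raise ValueError("no genes survive low-count filtering")
    return CountMatrix(counts.counts.loc[keep], counts.groups)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample, the median over reference genes (those with strictly
    positive counts in every sample, hence positive geometric mean) of
    count / geometric-mean(count across samples).
    """
    mat = counts.counts.to_numpy(dtype=float)
    usable = np.all(mat > 0, axis=1)
    if not usable.any():
        raise ValueError(
            "no reference genes with positive counts in every sample; "
            "cannot estimate size factors"
        )
    logmat = np.log(mat[usable])
    log_geomean = logmat.mean(axis=1)
    ratios = np.exp(logmat - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def vst_normalize(
    counts: CountMatrix, factors: pd.Series | None = None, mode: str = "log2p1"
) -> NormalizedMatrix:
    """Variance-stabilizing normalization: log2(count / size_factor + 1)."""
    if mode != "log2p1":
        raise ValueError(f"unknown VST mode: {mode!r}")
    if factors is None:
        factors = size_factors(counts)
    factors = pd.Series(factors).loc[counts.samples]
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    values = np.log2(counts.counts / factors + 1.0)
    return NormalizedMatrix(values, factors, counts.groups, mode=mode)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _group_arrays(counts: CountMatrix, normed: np.ndarray):
    ctrl = [i for i, s in enumerate(counts.samples) if counts.groups[s] == "control"]
    case = [i for i, s in enumerate(counts.samples) if counts.groups[s] == "case"]
    return normed[:, ctrl], normed[:, case]


def differential_expression(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
    lfc_cut: float = 0.585,
    dispersion_floor: str = "median",
) -> DEResult:
    """Negative-binomial Wald test of case vs control, gene by gene.

    Counts are normalized by median-of-ratios size factors; per-gene
    dispersion is estimated by method of moments from within-group
    variances and floored at 1e-8 plus, by default, at the median of the
    positive per-gene estimates (``dispersion_floor="none"`` disables the
    global floor).  The Wald statistic log2FC/SE is referred to a
    standard normal; BH adjustment runs over tested genes only.
    """
    from scipy import stats

    n_ctrl = len(counts.samples_in("control"))
    n_case = len(counts.samples_in("case"))
    if n_ctrl < 2 or n_case < 2:
        raise ValueError("need at least 2 samples per group")
    if factors is None:
        factors = size_factors(counts)
    factors = pd.Series(factors).loc[counts.samples]

    q = counts.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    q_ctrl, q_case = _group_arrays(counts, q)
    inv_s = 1.0 / factors.to_numpy()
    inv_ctrl, inv_case = _group_arrays(counts, np.broadcast_to(inv_s, q.shape))
    c_ctrl = inv_ctrl[0].mean()
    c_case = inv_case[0].mean()

    mean_ctrl = q_ctrl.mean(axis=1)
    mean_case = q_case.mean(axis=1)
    base_mean = q.mean(axis=1)
    tested = base_mean > 0

    # method-of-moments dispersion from pooled within-group variance:
    # Var(K/s) ~= mu * mean(1/s) + alpha * mu^2
    var_pool = (
        q_ctrl.var(axis=1, ddof=1) * (n_ctrl - 1) + q_case.var(axis=1, ddof=1) * (n_case - 1)
    ) / (n_ctrl + n_case - 2)
    mu_pool = (mean_ctrl * n_ctrl + mean_case * n_case) / (n_ctrl + n_case)
    c_pool = (c_ctrl * n_ctrl + c_case * n_case) / (n_ctrl + n_case)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_pool - mu_pool * c_pool) / mu_pool**2
    disp = np.where(np.isfinite(disp), disp, 0.0)
    raw_positive = disp[tested & (disp > 0)]
    disp = np.maximum(disp, 1e-8)
    if dispersion_floor == "median":
        if raw_positive.size:
            disp = np.maximum(disp, np.median(raw_positive))
    elif dispersion_floor != "none":
        raise ValueError(f"unknown dispersion_floor: {dispersion_floor!r}")

    zero_group = tested & ((mean_ctrl == 0) | (mean_case == 0))
    adj_ctrl = np.where(zero_group, mean_ctrl + 0.5, mean_ctrl)
    adj_case = np.where(zero_group, mean_case + 0.5, mean_case)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(tested, np.log2(adj_case / adj_ctrl), np.nan)
        se_ln = np.sqrt(
            (c_ctrl / adj_ctrl + disp) / n_ctrl + (c_case / adj_case + disp) / n_case
        )
    se = se_ln / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(tested & (se > 0), log2fc / se, np.nan)
    p = np.where(np.isfinite(wald), 2.0 * stats.norm.sf(np.abs(wald)), np.nan)

    padj = np.full(p.shape, np.nan)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": p,
            "padj": padj,
            "dispersion": disp,
            "tested": tested,
            "zero_group": zero_group,
        },
        index=counts.genes,
    )
    table["is_deg_up"] = (table["padj"] < alpha) & (table["log2fc"] > lfc_cut)
    table["is_deg_down"] = (table["padj"] < alpha) & (table["log2fc"] < -lfc_cut)
    return DEResult(table, alpha=alpha, lfc_cut=lfc_cut)


def call_degs(de: DEResult, alpha: float = 0.05, lfc_cut: float = 0.585):
    """DEG calls at strict thresholds: padj < alpha and |log2FC| > lfc_cut."""
    t = de.table
    up = t.index[(t["padj"] < alpha) & (t["log2fc"] > lfc_cut)].tolist()
    down = t.index[(t["padj"] < alpha) & (t["log2fc"] < -lfc_cut)].tolist()
    return up, down


def pca(norm: NormalizedMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of samples over gene-centered VST values."""
    from sklearn.decomposition import PCA as _PCA

    x = norm.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    total_var = centered.var(axis=0, ddof=1).sum()
    if total_var == 0:
        raise ValueError("matrix is constant; PCA undefined")
    max_comp = min(centered.shape[0] - 1, centered.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    fit = _PCA(n_components=k).fit(centered)
    scores = pd.DataFrame(
        fit.transform(centered),
        index=norm.samples,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(scores, np.asarray(fit.explained_variance_ratio_))
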