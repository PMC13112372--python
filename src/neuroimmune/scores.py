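"""Composite transcriptomic surrogates of systemic inflammation.

Bulk-brain expression cannot be phenotyped with a hemocytometer, so
peripheral inflammation indices are mimicked on the VST scale: marker
panels for myeloid/neutrophil-like activation (Sneu: S100a9, Fcgr3,
Csf3r), lymphoid activation (Slym: Lck, Zap70) and platelet-related
pathways (Splt: Itga2b, Gng11) are summed per sample, then combined as

    tNLR = log2((Sneu + 1) / (Slym + 1))
    tSII = log2(((Sneu + 1) * (Splt + 1)) / (Slym + 1))

alongside the hub gene Stat3 and the CRP surrogate Ptx3 on the same VST
scale.  Association between the hub and each index is quantified with a
Huber M-estimator regression (IRLS); the reported "weighted r" is the
Pearson correlation computed with the fit's final robustness weights,
and the p-value refers slope/SE to a t distribution with n-2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix

__all__ = [
    "MarkerPanel",
    "SurrogateScores",
    "RobustCorrResult",
    "gene_set_sum",
    "transcriptomic_nlr",
    "transcriptomic_sii",
    "score_samples",
    "robust_correlation",
    "correlate_hub_with_indices",
]

HUBER_C = 1.345


@dataclass(frozen=True)
class MarkerPanel:
    """Marker-gene panels defining the transcriptomic indices."""

    sneu_genes: tuple = ("S100a9", "Fcgr3", "Csf3r")
    slym_genes: tuple = ("Lck", "Zap70")
    splt_genes: tuple = ("Itga2b", "Gng11")
    crp_surrogate_gene: str = "Ptx3"
    hub_gene: str = "Stat3"
    aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        panels = [self.sneu_genes, self.slym_genes, self.splt_genes]
        if any(len(p) == 0 for p in panels):
            raise ValueError("marker panels must be nonempty")
        seen: set[str] = set()
        for p in panels:
            up = {g.upper() for g in p}
            if up & seen:
                raise ValueError("marker panels must be disjoint")
            seen |= up


def _resolve_genes(norm: NormalizedMatrix, genes, aliases: dict | None = None):
    """Case-insensitive symbol resolution with an optional alias table."""
    aliases = {k.upper(): v for k, v in (aliases or {}).items()}
    lookup: dict[str, str] = {}
    for g in norm.genes:
        lookup.setdefault(str(g).upper(), g)
    resolved, missing = [], []
    for g in genes:
        key = str(g).upper()
        key = str(aliases.get(key, key)).upper()
        if key in lookup:
            resolved.append(lookup[key])
        else:
            missing.append(g)
    if missing:
        raise KeyError(f"gene symbols not found in matrix: {missing}")
    return resolved


def gene_set_sum(norm: NormalizedMatrix, genes, aliases: dict | None = None) -> pd.Series:
    """Per-sample sum of VST values over a marker panel."""
    rows = _resolve_genes(norm, genes, aliases)
    return norm.values.loc[rows].sum(axis=0)


def transcriptomic_nlr(sneu, slym):
    """tNLR = log2((Sneu+1)/(Slym+1)); arguments must exceed -1."""
    sneu = np.asarray(sneu, dtype=float)
    slym = np.asarray(slym, dtype=float)
    if np.any(sneu <= -1) or np.any(slym <= -1):
        raise ValueError("panel sums must be > -1 for the log2 ratio")
    out = np.log2((sneu + 1.0) / (slym + 1.0))
    return out.item() if out.ndim == 0 else out


def transcriptomic_sii(sneu, slym, splt):
    """tSII = log2(((Sneu+1)*(Splt+1))/(Slym+1)); arguments must exceed -1."""
    sneu = np.asarray(sneu, dtype=float)
    slym = np.asarray(slym, dtype=float)
    splt = np.asarray(splt, dtype=float)
    if np.any(sneu <= -1) or np.any(slym <= -1) or np.any(splt <= -1):
        raise ValueError("panel sums must be > -1 for the log2 ratio")
    out = np.log2((sneu + 1.0) * (splt + 1.0) / (slym + 1.0))
    return out.item() if out.ndim == 0 else out


@dataclass
class SurrogateScores:
    """Per-sample panel sums, indices and hub/CRP-surrogate VST values."""

    table: pd.DataFrame  # columns: Sneu, Slym, Splt, tNLR, tSII, stat3_vst, ptx3_vst, group
    panel: MarkerPanel = field(default_factory=MarkerPanel)


def score_samples(norm: NormalizedMatrix, panel: MarkerPanel | None = None) -> SurrogateScores:
    """Assemble panel sums, tNLR, tSII, hub and CRP-surrogate VST per sample."""
    panel = panel or MarkerPanel()
    sneu = gene_set_sum(norm, panel.sneu_genes, panel.aliases)
    slym = gene_set_sum(norm, panel.slym_genes, panel.aliases)
    splt = gene_set_sum(norm, panel.splt_genes, panel.aliases)
    hub = norm.values.loc[_resolve_genes(norm, [panel.hub_gene], panel.aliases)[0]]
    crp = norm.values.loc[_resolve_genes(norm, [panel.crp_surrogate_gene], panel.aliases)[0]]
    table = pd.DataFrame(
        {
            "Sneu": sneu,
            "Slym": slym,
            "Splt": splt,
            "tNLR": transcriptomic_nlr(sneu.to_numpy(), slym.to_numpy()),
            "tSII": transcriptomic_sii(sneu.to_numpy(), slym.to_numpy(), splt.to_numpy()),
            "stat3_vst": hub,
            "ptx3_vst": crp,
            "group": norm.groups.loc[norm.samples],
        }
    )
    return SurrogateScores(table, panel)


@dataclass
class RobustCorrResult:
    slope: float
    intercept: float
    slope_se: float
    robust_t: float
    p: float
    weights: np.ndarray
    weighted_r: float
    n: int
    n_iter: int = 0


def _weighted_linear_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line fit; returns (slope, intercept, slope_se)."""
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (x - xb) ** 2).sum()
    sxy = (w * (x - xb) * (y - yb)).sum()
    if sxx == 0:
        raise ValueError("x is constant (zero weighted variance)")
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    df = sw - 2.0
    s2 = (w * resid**2).sum() / df if df > 0 else np.nan
    se = math.sqrt(max(s2, 0.0) / sxx) if np.isfinite(s2) else np.nan
    return slope, intercept, se


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    cov = (w * (x - xb) * (y - yb)).sum()
    vx = (w * (x - xb) ** 2).sum()
    vy = (w * (y - yb) ** 2).sum()
    if vx == 0 or vy == 0:
        raise ValueError("constant input in weighted correlation")
    return float(cov / math.sqrt(vx * vy))


def robust_correlation(
    x,
    y,
    max_iter: int = 50,
    tol: float = 1e-8,
    force_weights: np.ndarray | None = None,
) -> RobustCorrResult:
    """Huber M-estimator regression of y on x with IRLS, plus weighted r.

    Tuning constant 1.345 times the MAD scale of residuals (rescaled to
    be consistent for Gaussian errors); ``force_weights`` bypasses IRLS
    and fits a single weighted least-squares pass (used to verify the
    OLS limit).
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("robust correlation needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")

    if force_weights is not None:
        w = np.asarray(force_weights, dtype=float)
        slope, intercept, se = _weighted_linear_fit(x, y, w)
        n_iter = 0
    else:
        w = np.ones(n)
        slope, intercept, se = _weighted_linear_fit(x, y, w)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            resid = y - intercept - slope * x
            scale = np.median(np.abs(resid - np.median(resid))) / 0.6744897501960817
            if scale <= tol * max(1.0, float(np.abs(y).max())):
                w = np.ones(n)  # (near-)perfect fit: all points trusted
                slope, intercept, se = _weighted_linear_fit(x, y, w)
                break
            c = HUBER_C * scale
            absr = np.abs(resid)
            with np.errstate(divide="ignore"):
                w = np.where(absr <= c, 1.0, c / absr)
            new_slope, new_intercept, se = _weighted_linear_fit(x, y, w)
            delta = max(abs(new_slope - slope), abs(new_intercept - intercept))
            slope, intercept = new_slope, new_intercept
            if delta < tol * max(1.0, abs(slope), abs(intercept)):
                break

    r = weighted_pearson(x, y, w)
    if se is not None and np.isfinite(se) and se > 0:
        t_stat = slope / se
        p = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
    else:  # exact fit
        t_stat = math.copysign(math.inf, slope) if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    return RobustCorrResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(se),
        robust_t=float(t_stat),
        p=float(p),
        weights=w,
        weighted_r=r,
        n=n,
        n_iter=n_iter,
    )


def correlate_hub_with_indices(scores: SurrogateScores) -> dict[str, RobustCorrResult]:
    """Robust correlation of hub-gene VST with tNLR, tSII and the CRP
    surrogate, pooled across groups."""
    t = scores.table
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    x = t["stat3_vst"].to_numpy()
    return {
        "tNLR": robust_correlation(x, t["tNLR"].to_numpy()),
        "tSII": robust_correlation(x, t["tSII"].to_numpy()),
        "ptx3": robust_correlation(x, t["ptx3_vst"].to_numpy()),
    }
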