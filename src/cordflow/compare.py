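"""Cross-modality comparison of spatial profiles.

The non-contrast velocity index (AU) and the contrast washout decay constant
(1/s) are different physical surrogates of the same flow; no linear
relationship between them is assumed.  Agreement is therefore measured with
Spearman's rank correlation over shared distance bins, computed per subject,
and averaged across subjects in Fisher z-space (arctanh), the standard way
to average correlation coefficients with unequal per-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import SpatialProfile

__all__ = [
    "CorrelationResult",
    "spearman_profiles",
    "fisher_z_mean",
    "profile_discrepancy",
    "pooled_spearman",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Rank correlation between two profiles over shared bins."""

    rho: float
    p_value: float
    n_bins: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("|rho| must not exceed 1")


def _paired_values(a: SpatialProfile, b: SpatialProfile) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_grid(b):
        raise ValueError("profiles must share an identical bin grid")
    ok = np.isfinite(a.index_values) & np.isfinite(b.index_values)
    return a.index_values[ok], b.index_values[ok]


def spearman_profiles(a: SpatialProfile, b: SpatialProfile) -> CorrelationResult:
    """Spearman rank correlation of two profiles on a shared bin grid.

    Bins missing in either profile are dropped pairwise; ties receive
    average ranks; the p-value is two-sided.  Fewer than 3 shared bins is an
    error (no defined p-value).
    """
    x, y = _paired_values(a, b)
    if x.size < 3:
        raise ValueError(f"only {x.size} shared bins; need at least 3")
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def fisher_z_mean(rhos) -> float:
    """Average correlations via Fisher's z transform: tanh(mean(atanh ρ)).

    Each |ρ| must be strictly below 1 (atanh diverges at ±1); callers may
    clip toward ±(1 − ε) beforehand, with a warning, if a perfect correlation
    occurs.
    """
    rhos = np.asarray(rhos, dtype=float)
    if rhos.size == 0:
        raise ValueError("no correlations to average")
    if np.any(np.abs(rhos) >= 1.0):
        raise ValueError("|rho| = 1 cannot be averaged in z-space; clip first")
    return float(np.tanh(np.mean(np.arctanh(rhos))))


def pooled_spearman(pairs: list[tuple[SpatialProfile, SpatialProfile]]) -> CorrelationResult:
    """Single rank correlation over all subjects' bins pooled together.

    Exposed as an alternative to per-subject correlation + Fisher-z
    averaging; pooling hides inter-subject variability and is not the
    default.
    """
    xs, ys = [], []
    for a, b in pairs:
        x, y = _paired_values(a, b)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ValueError("need at least 3 pooled bins")
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def profile_discrepancy(a: SpatialProfile, b: SpatialProfile) -> np.ndarray:
    """Per-bin absolute difference of the two profiles after rescaling.

    The two modalities carry different units (AU vs 1/s), so each profile is
    first rescaled to [0, 1] by its own maximum — a package convention,
    stated prominently: discrepancies are comparable only under this
    normalization.  Bins missing in either profile are NaN.
    """
    if not a.same_grid(b):
        raise ValueError("profiles must share an identical bin grid")
    amax = np.nanmax(a.index_values)
    bmax = np.nanmax(b.index_values)
    if not (amax > 0) or not (bmax > 0):
        raise ValueError("cannot rescale a profile whose maximum is zero")
    return np.abs(a.index_values / amax - b.index_values / bmax)
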