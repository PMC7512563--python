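"""Shannon and Tsallis entropy of coefficient gray-level histograms.

Each wavelet sub-band is summarized by one number: the Tsallis entropy

    S_q = (1 - sum_i p_i^q) / (q - 1),    q > 0, q != 1,

of its gray-level histogram, where p_i is the proportion of coefficients
falling in gray level i and q is the non-extensive parameter.  As q -> 1
S_q converges to the Shannon entropy S = -sum_i p_i log p_i (natural log).
q < 1 emphasises rare gray levels, q > 1 the dominant ones; brain tissue,
with its long-range correlations and approximately fractal structure, is
the kind of system non-extensive entropy was designed for, and the best q
is treated as a hyperparameter to be searched rather than fixed a priori.

Coefficients are mapped to gray levels by min-max scaling onto ``n_bins``
integer bins (256 by default, mirroring 8-bit gray levels).  A J-level
pyramid yields a feature vector of 3J + 1 entropies, ordered
[LL_J, HL_1, LH_1, HH_1, ..., HL_J, LH_J, HH_J].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wavelet import WaveletPyramid

#: below this distance from 1, S_q is evaluated as the Shannon limit
_Q_ONE_EPS = 1e-9


@dataclass(frozen=True)
class GrayHistogram:
    """A discrete gray-level distribution: p_i >= 0 summing to one."""

    probabilities: np.ndarray
    n_bins: int

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or len(p) != self.n_bins:
            raise ValueError("probabilities length must equal n_bins")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class FeatureVector:
    """Per-sub-band Tsallis entropies (nats) at one value of q."""

    values: np.ndarray
    q_used: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def coeff_histogram(matrix: np.ndarray, n_bins: int = 256) -> GrayHistogram:
    """Min-max scale coefficients onto gray levels 0..n_bins-1 and count.

    A constant matrix has no dynamic range; all its mass goes to bin 0.
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty coefficient matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("coefficient matrix contains non-finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    counts = _bin_counts(m.ravel(), n_bins)
    return GrayHistogram(counts / m.size, n_bins)


def _bin_counts(v: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        counts = np.zeros(n_bins)
        counts[0] = v.size
        return counts
    idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(int)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return np.bincount(idx, minlength=n_bins).astype(float)


def shannon_entropy(hist: GrayHistogram, base: float = 2.0) -> float:
    """S = -sum p_i log_base(p_i), zero-probability bins skipped."""
    p = hist.probabilities
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / math.log(base))


def tsallis_entropy(hist: GrayHistogram, q: float) -> float:
    """S_q = (1 - sum p_i^q)/(q - 1); at q ~ 1 the Shannon limit (nats)."""
    if q <= 0:
        raise ValueError(f"non-extensive parameter q must be > 0, got {q}")
    if abs(q - 1.0) < _Q_ONE_EPS:
        return shannon_entropy(hist, base=math.e)
    p = hist.probabilities
    p = p[p > 0]
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def pseudo_additivity_gap(
    hist_a: GrayHistogram, hist_b: GrayHistogram, q: float
) -> float:
    """Residual of the Tsallis composition rule for independent systems.

    For the product distribution p_ij = p_i p_j the identity
    S_q(A+B) = S_q(A) + S_q(B) + (1-q) S_q(A) S_q(B) holds exactly; the
    returned gap should be numerically zero.
    """
    joint = np.outer(hist_a.probabilities, hist_b.probabilities).ravel()
    joint_hist = GrayHistogram(joint, len(joint))
    sa = tsallis_entropy(hist_a, q)
    sb = tsallis_entropy(hist_b, q)
    sab = tsallis_entropy(joint_hist, q)
    return sab - (sa + sb + (1.0 - q) * sa * sb)


def subband_histograms(
    pyramid: WaveletPyramid, n_bins: int = 256
) -> list[GrayHistogram]:
    """One gray-level histogram per sub-band, in feature order.

    Histograms do not depend on q, so they can be computed once per image
    and reused while q is being searched.
    """
    return [coeff_histogram(band, n_bins) for _, band in pyramid.subbands()]


def tsallis_from_histograms(
    hists: list[GrayHistogram], q: float
) -> np.ndarray:
    return np.array([tsallis_entropy(h, q) for h in hists])


def extract_features(
    pyramid: WaveletPyramid, q: float, n_bins: int = 256
) -> FeatureVector:
    """Tsallis entropy of every sub-band of a pyramid (3J + 1 values)."""
    values = tsallis_from_histograms(subband_histograms(pyramid, n_bins), q)
    return FeatureVector(values, q_used=q)
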