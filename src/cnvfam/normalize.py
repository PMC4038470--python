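"""Intensity normalization for two-channel aCGH data.

Six normalization schemes are supported, combining the raw log-ratio with
quantile normalization (QNorm) of either the individual channels or the
log-ratio itself, plus two pseudo-count variants defined at ratio zero:

    1. log2(R/G)
    2. log2(QNorm(R)/QNorm(G))
    3. QNorm(log2(R/G))
    4. QNorm(log2(QNorm(R)/QNorm(G)))
    5. log2(R/G + 0.5)
    6. log2(QNorm(R)/QNorm(G) + 0.5)

QNorm equalizes distributions *across samples*: every sample's value vector
is mapped onto the cohort-mean order-statistic vector by within-sample rank.
Logs are base 2 (the aCGH convention); entries undefined under a scheme
(zero denominators, zero ratios under schemes 1-4) become NaN and propagate
to summarization as missing.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .datatypes import IntensityMatrix

logger = logging.getLogger(__name__)

N_SCHEMES = 6

SCHEME_LABELS = {
    1: "log2(R/G)",
    2: "log2(QNorm(R)/QNorm(G))",
    3: "QNorm(log2(R/G))",
    4: "QNorm(log2(QNorm(R)/QNorm(G)))",
    5: "log2(R/G + 0.5)",
    6: "log2(QNorm(R)/QNorm(G) + 0.5)",
}


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows (samples) to the cohort-mean distribution.

    Each sample's values are replaced by the mean order-statistic vector,
    assigned by within-sample rank; ties receive the average of the tied
    target values. Missing entries (NaN) are ignored when ranking and remain
    missing; samples with differing missingness are aligned on a common
    quantile grid by linear interpolation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x probes matrix")
    n, m = X.shape
    if n < 2:
        logger.warning("quantile_normalize: single sample, returning identity")
        return X.copy()

    grid = np.linspace(0.0, 1.0, m)
    ref = np.zeros(m)
    n_used = 0
    for i in range(n):
        vals = np.sort(X[i][np.isfinite(X[i])])
        if vals.size == 0:
            continue
        pos = np.linspace(0.0, 1.0, vals.size) if vals.size > 1 else np.array([0.5])
        ref += np.interp(grid, pos, vals)
        n_used += 1
    if n_used == 0:
        return X.copy()
    ref /= n_used

    out = np.full_like(X, np.nan)
    for i in range(n):
        mask = np.isfinite(X[i])
        k = int(mask.sum())
        if k == 0:
            continue
        ranks = rankdata(X[i][mask], method="average")
        pos = (ranks - 1.0) / (k - 1.0) if k > 1 else np.array([0.5])
        out[i, mask] = np.interp(pos, grid, ref)
    return out


def _log_ratio(R: np.ndarray, G: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """log2 of the channel ratio; NaN where undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(G > 0, R / np.where(G > 0, G, 1.0), np.nan)
        val = np.log2(ratio + pseudocount)
    val[~np.isfinite(val)] = np.nan
    return val


def normalize(intensity: IntensityMatrix, scheme: int) -> IntensityMatrix:
    """Apply one of the six normalization schemes.

    Returns a new :class:`IntensityMatrix` with ``normalized`` filled on the
    log2 scale and ``norm_scheme`` recorded. QNorm is applied across samples
    per channel (schemes 2, 4, 6) and/or across samples on the log-ratio
    (schemes 3, 4), following the composition order of the scheme name.
    """
    if scheme not in SCHEME_LABELS:
        raise ValueError(f"normalization scheme must be 1..{N_SCHEMES}, got {scheme}")
    R, G = intensity.R, intensity.G
    if scheme in (2, 4, 6):
        R, G = quantile_normalize(R), quantile_normalize(G)
    if scheme in (1, 2):
        norm = _log_ratio(R, G)
    elif scheme in (3, 4):
        norm = quantile_normalize(_log_ratio(R, G))
    else:  # 5, 6
        norm = _log_ratio(R, G, pseudocount=0.5)
    # masking is decided on the *raw* channels: quantile normalization would
    # otherwise silently remap true zeros onto positive reference values
    if scheme in (1, 2, 3, 4):
        norm[(intensity.R == 0) | (intensity.G == 0)] = np.nan
    else:
        norm[intensity.G == 0] = np.nan
    return IntensityMatrix(
        sample_ids=list(intensity.sample_ids),
        probe_ids=list(intensity.probe_ids),
        R=intensity.R,
        G=intensity.G,
        normalized=norm,
        norm_scheme=scheme,
    )


def normalize_all_schemes(intensity: IntensityMatrix) -> dict[int, IntensityMatrix]:
    """Compute all six normalizations once (used by pipeline selection)."""
    return {s: normalize(intensity, s) for s in range(1, N_SCHEMES + 1)}
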