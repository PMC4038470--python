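"""Copy-number genotype calling by one-dimensional Gaussian mixtures.

Per-CNV summary scores are clustered with an EM-fitted univariate Gaussian
mixture; the number of components K is chosen by BIC over K = 1..K_max with
multiple quantile-seeded restarts. A locus is "clusterable" when the fitted
mixture has K >= 2 components and nearly all samples receive a confident
(posterior > 0.95) assignment — loci failing this are still testable by the
intensity-based family test, which is the point of the workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GenotypeCalls:
    """Fitted mixture and per-sample posterior copy-number class calls."""

    cnv_id: str
    K: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # n_samples x K, rows sum to 1
    hard_call: np.ndarray  # int class index, -1 = no confident call
    call_rate: float
    clusterable: bool
    loglik: float
    bic: float
    bic_by_k: dict[int, float] = field(default_factory=dict)
    confidence: float = 0.95


def _em_run(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
):
    """Run EM to convergence; prune components that degenerate.

    The log-likelihood is asserted non-decreasing at every iteration (a core
    EM guarantee; violation would indicate an implementation bug). Components
    whose SD collapses below 1e-6 of the data SD, or whose weight vanishes,
    are removed and the fit continues with fewer components.
    """
    x = np.asarray(x, float)
    n = x.size
    sd_floor = 1e-6 * max(np.std(x), 1e-12)
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_dens = (
            np.log(weights)[None, :]
            - np.log(sds)[None, :]
            - 0.5 * _LOG_2PI
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        row_ll = logsumexp(log_dens, axis=1)
        ll = float(row_ll.sum())
        assert ll >= prev_ll - 1e-6 * max(1.0, abs(ll)), "EM log-likelihood decreased"
        resp = np.exp(log_dens - row_ll[:, None])
        nk = resp.sum(axis=0)
        degenerate = nk < 1e-8
        if not degenerate.any():
            new_means = (resp * x[:, None]).sum(axis=0) / nk
            new_sds = np.sqrt((resp * (x[:, None] - new_means[None, :]) ** 2).sum(axis=0) / nk)
            degenerate = new_sds < sd_floor
        if degenerate.any():
            keep = ~degenerate
            if keep.sum() == 0:
                keep[np.argmax(nk)] = True
            logger.debug("EM: pruning %d degenerate component(s)", int(degenerate.sum()))
            means, sds, weights = means[keep], sds[keep], weights[keep]
            weights = weights / weights.sum()
            prev_ll = -np.inf  # likelihood not comparable across model sizes
            continue
        means, sds = new_means, new_sds
        weights = nk / n
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return means, sds, weights, prev_ll


def _loglik(x, means, sds, weights):
    log_dens = (
        np.log(weights)[None, :]
        - np.log(sds)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
    )
    return float(logsumexp(log_dens, axis=1).sum()), log_dens


def fit_mixture(
    scores,
    K_max: int = 6,
    n_restarts: int = 10,
    seed: int | None = None,
    cnv_id: str = "",
    confidence: float = 0.95,
) -> GenotypeCalls:
    """Fit univariate Gaussian mixtures for K = 1..K_max and select by BIC.

    Restart 0 seeds component means at evenly spaced within-sample quantiles;
    further restarts jitter the quantile positions (k-means++-flavoured
    spread seeding on order statistics). Deterministic given ``seed``.
    Components are reported sorted by ascending mean, so class indices are
    ordinal in intensity.
    """
    x = np.asarray(scores, float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 30:
        raise ValueError(f"need >=30 scored samples to fit a mixture, got {n}")
    rng = np.random.default_rng(seed)
    data_sd = max(np.std(x), 1e-12)

    best = None
    bic_by_k: dict[int, float] = {}
    for K in range(1, K_max + 1):
        best_k = None
        for r in range(max(1, n_restarts)):
            if r == 0:
                q = (np.arange(K) + 0.5) / K
            else:
                q = np.sort(rng.uniform(0.02, 0.98, size=K))
            means0 = np.quantile(x, q)
            sds0 = np.full(K, max(data_sd / max(K, 1), 1e-8))
            w0 = np.full(K, 1.0 / K)
            means, sds, weights, ll = _em_run(x, means0, sds0, w0)
            if best_k is None or ll > best_k[-1]:
                best_k = (means, sds, weights, ll)
        means, sds, weights, ll = best_k
        k_eff = len(means)
        n_par = 3 * k_eff - 1
        bic = -2.0 * ll + n_par * np.log(n)
        bic_by_k[K] = bic
        if best is None or bic < best[0]:
            best = (bic, means, sds, weights, ll)

    bic, means, sds, weights, ll = best
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    full_x = np.asarray(scores, float)
    finite = np.isfinite(full_x)
    post = np.full((full_x.size, len(means)), np.nan)
    if finite.any():
        _, log_dens = _loglik(full_x[finite], means, sds, weights)
        post[finite] = np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])

    calls = GenotypeCalls(
        cnv_id=cnv_id,
        K=len(means),
        means=means,
        sds=sds,
        weights=weights,
        posteriors=post,
        hard_call=np.full(full_x.size, -1, dtype=int),
        call_rate=0.0,
        clusterable=False,
        loglik=ll,
        bic=bic,
        bic_by_k=bic_by_k,
        confidence=confidence,
    )
    hard_calls(calls, confidence=confidence)
    calls.clusterable = assess_clusterability(calls)
    return calls


def hard_calls(calls: GenotypeCalls, confidence: float = 0.95) -> np.ndarray:
    """Assign a discrete class where the max posterior exceeds ``confidence``.

    Samples below the threshold stay uncalled (-1); ``call_rate`` is the
    called fraction among samples with finite scores.
    """
    post = calls.posteriors
    finite = np.isfinite(post).all(axis=1)
    hard = np.full(post.shape[0], -1, dtype=int)
    if finite.any():
        maxp = post[finite].max(axis=1)
        argp = post[finite].argmax(axis=1)
        called = maxp > confidence
        idx = np.where(finite)[0]
        hard[idx[called]] = argp[called]
    calls.hard_call = hard
    n_finite = int(finite.sum())
    calls.call_rate = float((hard >= 0).sum() / n_finite) if n_finite else 0.0
    calls.confidence = confidence
    return hard


def assess_clusterability(
    calls: GenotypeCalls,
    posterior_threshold: float = 0.95,
    min_confident_fraction: float = 0.95,
) -> bool:
    """A locus clusters when K >= 2 and >=95% of samples are confidently assigned."""
    if calls.K < 2:
        return False
    post = calls.posteriors
    finite = np.isfinite(post).all(axis=1)
    if not finite.any():
        return False
    frac = float((post[finite].max(axis=1) > posterior_threshold).mean())
    return frac >= min_confident_fraction
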