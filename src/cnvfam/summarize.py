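"""Multi-probe CNV summarization: PCA, heritability probe scaling, pipeline selection.

A CNV region is measured by several probes; per-sample summary scores are
obtained by principal component analysis of the mean-centered (but *not*
variance-scaled) probe block. Because the family design provides an internal
signal-quality criterion — the correlation between affected offspring and
mid-parental summary values ("heritability") — probes can additionally be
weighted by their own offspring-midparent correlation before PCA
(heritability probe scaling, HPS), and the best of the 12 candidate
pipelines (6 normalization schemes x {pca, hps_pca}) is chosen per locus as
the one maximizing that heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortTables, IntensityMatrix
from .normalize import normalize_all_schemes

logger = logging.getLogger(__name__)

SUMMARY_METHODS = ("pca", "hps_pca")


@dataclass
class CnvSummary:
    """Per-sample summary scores for one CNV region."""

    cnv_id: str
    component_scores: pd.DataFrame  # samples x k, columns PC1..PCk
    loadings: pd.DataFrame  # probes x k
    pipeline: tuple[int, str] = (1, "pca")  # (norm scheme index, summary method)
    heritability: float = float("nan")
    explained_variance: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def pc1(self) -> pd.Series:
        return self.component_scores.iloc[:, 0]


@dataclass
class HpsWeights:
    """Per-probe heritability weights (offspring-midparent correlation, clipped at 0)."""

    cnv_id: str
    weights: pd.Series  # indexed by probe_id, values in [0, 1]


def pca_summary(
    block: pd.DataFrame,
    k: int = 1,
    cnv_id: str = "",
    max_missing: float = 0.2,
) -> CnvSummary:
    """Summarize a samples x probes block by unscaled PCA.

    Probe columns are mean-centered but not scaled to unit variance, so
    probes with larger dynamic range contribute more — intentional, since
    copy-number response, not per-probe noise, should dominate. Probes with
    more than ``max_missing`` missing entries are dropped; remaining missing
    entries contribute nothing to the covariance (pairwise-complete) and are
    mean-imputed (i.e. zero after centering) for scoring.

    PC1's sign is oriented so that its correlation with the across-probe mean
    signal is nonnegative; higher components are oriented by their largest
    absolute loading.
    """
    if block.shape[1] < 1:
        raise ValueError("need at least one probe")
    if block.shape[0] < 3:
        raise ValueError("need at least three samples")
    keep = block.columns[block.isna().mean(axis=0) <= max_missing]
    n_dropped = block.shape[1] - len(keep)
    if n_dropped:
        logger.info("pca_summary %s: dropped %d probes with >%d%% missing",
                    cnv_id, n_dropped, int(100 * max_missing))
    if len(keep) == 0:
        raise ValueError(f"all probes dropped for locus {cnv_id}")
    block = block[keep]

    centered = block - block.mean(axis=0)
    cov = block.cov().to_numpy()  # pairwise-complete covariance
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k_eff = min(k, len(keep))
    if k_eff < k:
        logger.warning("pca_summary %s: k truncated from %d to rank %d", cnv_id, k, k_eff)
    loadings = evecs[:, :k_eff]

    filled = centered.fillna(0.0).to_numpy()
    scores = filled @ loadings
    scores -= scores.mean(axis=0)

    probe_mean = np.nanmean(centered.to_numpy(), axis=1)
    for j in range(k_eff):
        if j == 0:
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(scores[:, 0], probe_mean)[0, 1]
            flip = np.isfinite(c) and c < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    cols = [f"PC{i + 1}" for i in range(k_eff)]
    return CnvSummary(
        cnv_id=cnv_id,
        component_scores=pd.DataFrame(scores, index=block.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=keep, columns=cols),
        explained_variance=evals[:k_eff].copy(),
    )


def heritability_score(scores: pd.Series, cohort: CohortTables) -> float:
    """Pearson correlation between affected-offspring and mid-parental scores.

    Computed over all affected-offspring trios with complete scores; this is
    the pipeline-selection criterion and mirrors the transmissions used by
    the association test. Returns NaN with fewer than two complete trios.
    """
    trios = cohort.affected_trios()
    if trios.empty:
        return float("nan")
    off = scores.reindex(trios["offspring"]).to_numpy()
    mid = (
        scores.reindex(trios["father"]).to_numpy()
        + scores.reindex(trios["mother"]).to_numpy()
    ) / 2.0
    ok = np.isfinite(off) & np.isfinite(mid)
    if ok.sum() < 2:
        return float("nan")
    off, mid = off[ok], mid[ok]
    if np.std(off) == 0 or np.std(mid) == 0:
        return float("nan")
    return float(np.corrcoef(off, mid)[0, 1])


def hps_weights(block: pd.DataFrame, cohort: CohortTables, cnv_id: str = "") -> HpsWeights:
    """Per-probe offspring-midparent correlations, clipped at zero.

    A probe whose intensity is heritable (offspring track mid-parent) earns
    weight up to 1; uninformative or anti-correlated probes earn 0.
    """
    w = {}
    for p in block.columns:
        h = heritability_score(block[p], cohort)
        w[p] = max(0.0, h) if np.isfinite(h) else 0.0
    return HpsWeights(cnv_id=cnv_id, weights=pd.Series(w))


def hps_pca_summary(
    block: pd.DataFrame,
    cohort: CohortTables,
    k: int = 1,
    cnv_id: str = "",
) -> CnvSummary:
    """Heritability-probe-scaled PCA: weight probes by heritability, then PCA."""
    w = hps_weights(block, cohort, cnv_id=cnv_id).weights
    if (w == 0).all():
        logger.warning("hps_pca %s: all probe weights zero, falling back to PCA", cnv_id)
        out = pca_summary(block, k=k, cnv_id=cnv_id)
    else:
        out = pca_summary(block * w, k=k, cnv_id=cnv_id)
    out.pipeline = (out.pipeline[0], "hps_pca")
    return out


def summarize_block(
    normalized: IntensityMatrix,
    probe_ids: list[str],
    cohort: CohortTables | None,
    method: str = "pca",
    k: int = 1,
    cnv_id: str = "",
) -> CnvSummary:
    """Summarize one CNV's probes from a normalized intensity matrix."""
    if method not in SUMMARY_METHODS:
        raise ValueError(f"unknown summary method {method!r}")
    frame = normalized.normalized_frame()[probe_ids]
    if method == "pca":
        out = pca_summary(frame, k=k, cnv_id=cnv_id)
    else:
        if cohort is None:
            raise ValueError("hps_pca requires a cohort")
        out = hps_pca_summary(frame, cohort, k=k, cnv_id=cnv_id)
    out.pipeline = (normalized.norm_scheme or 0, method)
    return out


def select_pipeline(
    intensity: IntensityMatrix,
    probes: pd.DataFrame,
    cohort: CohortTables,
    cnv_id: str,
    k: int = 1,
    normalized_cache: dict[int, IntensityMatrix] | None = None,
) -> CnvSummary:
    """Choose, per CNV, the most heritable of the 12 candidate pipelines.

    All 6 normalization schemes x {pca, hps_pca} are evaluated; the summary
    with maximal offspring-midparent correlation wins. Exact ties break to
    the lowest (scheme index, summary method) pair. ``probes`` is the probe
    annotation table (columns probe_id, cnv_id, probe_class); breakpoint
    probes are excluded from quantitative summarization.
    """
    mask = (probes["cnv_id"] == cnv_id) & (
        probes.get("probe_class", "internal_quantitative") == "internal_quantitative"
    )
    probe_ids = [p for p in probes.loc[mask, "probe_id"] if p in set(intensity.probe_ids)]
    if not probe_ids:
        raise ValueError(f"no quantitative probes for locus {cnv_id}")
    if normalized_cache is None:
        normalized_cache = normalize_all_schemes(intensity)

    candidates: list[tuple[float, int, int, CnvSummary]] = []
    for scheme in sorted(normalized_cache):
        for mi, method in enumerate(SUMMARY_METHODS):
            try:
                summ = summarize_block(
                    normalized_cache[scheme], probe_ids, cohort,
                    method=method, k=k, cnv_id=cnv_id,
                )
            except ValueError:
                continue
            h = heritability_score(summ.pc1, cohort)
            summ.heritability = h
            logger.debug("select_pipeline %s scheme=%d method=%s h=%.4f",
                         cnv_id, scheme, method, h)
            if np.isfinite(h):
                candidates.append((h, scheme, mi, summ))
    if not candidates:
        raise ValueError(f"no pipeline evaluable for locus {cnv_id} (too few trios)")
    # max h; ties broken by lowest (scheme, method) pair
    best = max(candidates, key=lambda t: (t[0], -t[1], -t[2]))
    return best[3]
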