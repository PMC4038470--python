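"""Detection of somatic-rearrangement artifacts in CNV intensity data.

Loci in somatically rearranging regions (T-cell receptor, immunoglobulin
heavy chain) can show apparent transmission distortion that is really an
age-at-sampling effect: blood cell-type composition drifts with age, and
offspring are systematically younger than their parents. This module scans
each locus for (i) an age-intensity correlation within blood-derived DNA
(with a cubic-spline fit per DNA source for reporting, and a repeat within
offspring only) and (ii) a blood-vs-cell-line mean intensity difference.
Flagging is advisory: family-based tests are robust to the source
difference (DNA source is homogeneous within families) but not to the age
trend, so a locus that is both strongly associated and age-correlated is
interpreted as an artifact rather than a disease signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from .datatypes import CohortTables

logger = logging.getLogger(__name__)


@dataclass
class ArtifactResult:
    """Per-locus artifact scan outcome."""

    cnv_id: str
    age_corr_blood: float = float("nan")
    age_trend_p: float = float("nan")
    age_corr_offspring: float = float("nan")
    age_trend_p_offspring: float = float("nan")
    source_diff: float = float("nan")
    source_p: float = float("nan")
    spline_fits: dict = field(default_factory=dict)
    age_tested: bool = False
    source_tested: bool = False
    flagged: bool = False


def _spline_fit(age: np.ndarray, y: np.ndarray, n_knots: int = 4):
    """Natural cubic spline fit of score on age; knots at age quintiles."""
    if len(age) < n_knots + 3 or np.unique(age).size < n_knots + 2:
        return None
    knots = np.quantile(age, np.linspace(0, 1, n_knots + 2)[1:-1])
    try:
        X = np.asarray(dmatrix(
            "cr(x, knots=knots)", {"x": age, "knots": knots}, return_type="matrix"
        ))
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return {"knots": knots, "coef": coef, "fitted": X @ coef}
    except Exception:  # degenerate designs on tiny strata
        return None


def age_intensity_scan(
    scores: pd.Series,
    cohort: CohortTables,
    cnv_id: str = "",
    min_blood: int = 50,
) -> ArtifactResult:
    """Correlation between age at sampling and summary score in blood DNA.

    Pearson correlation and its P-value within blood-derived samples; the
    same test repeated within offspring only (a within-generation trend
    rules out a parent/offspring confound); natural cubic spline fits per
    DNA source retained for reporting. Untested when age data are missing,
    constant, or blood samples number fewer than ``min_blood``.
    """
    res = ArtifactResult(cnv_id=cnv_id)
    meta = cohort.samples.reindex(scores.index)
    age = meta["age_at_sampling"].to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)
    blood = (meta["dna_source"] == "blood").to_numpy()
    ok = np.isfinite(age) & np.isfinite(y)

    sel = ok & blood
    if sel.sum() < min_blood or np.unique(age[sel]).size < 2:
        logger.info("age scan %s: untested (blood n=%d)", cnv_id, int(sel.sum()))
        return res
    r, p = stats.pearsonr(age[sel], y[sel])
    res.age_corr_blood, res.age_trend_p = float(r), float(p)
    res.age_tested = True

    off = meta["affected"].to_numpy(dtype=bool)
    sel_off = sel & off
    if sel_off.sum() >= 10 and np.unique(age[sel_off]).size >= 2:
        r2, p2 = stats.pearsonr(age[sel_off], y[sel_off])
        res.age_corr_offspring, res.age_trend_p_offspring = float(r2), float(p2)

    for src in ("blood", "lcl"):
        m = ok & (meta["dna_source"] == src).to_numpy()
        fit = _spline_fit(age[m], y[m]) if m.sum() >= 10 else None
        if fit is not None:
            res.spline_fits[src] = {"knots": fit["knots"], "coef": fit["coef"]}
    return res


def source_difference_scan(
    scores: pd.Series,
    cohort: CohortTables,
    cnv_id: str = "",
    min_each: int = 20,
) -> ArtifactResult:
    """Welch comparison of summary scores between cell-line and blood DNA.

    Family-based association tests are robust to this difference (DNA source
    is constant within families), so this scan is diagnostic, not exclusionary.
    """
    res = ArtifactResult(cnv_id=cnv_id)
    meta = cohort.samples.reindex(scores.index)
    y = scores.to_numpy(dtype=float)
    ok = np.isfinite(y)
    lcl = y[ok & (meta["dna_source"] == "lcl").to_numpy()]
    blood = y[ok & (meta["dna_source"] == "blood").to_numpy()]
    if len(lcl) < min_each or len(blood) < min_each:
        logger.info("source scan %s: untested (blood=%d, lcl=%d)",
                    cnv_id, len(blood), len(lcl))
        return res
    t, p = stats.ttest_ind(lcl, blood, equal_var=False)
    res.source_diff = float(np.mean(lcl) - np.mean(blood))
    res.source_p = float(p)
    res.source_tested = True
    return res


def scan_loci(
    score_map: dict[str, pd.Series],
    cohort: CohortTables,
    alpha: float = 0.05,
    min_blood: int = 50,
) -> dict[str, ArtifactResult]:
    """Age- and source-scan every locus; Bonferroni-flag age trends.

    A locus is flagged when its blood age-trend P-value falls below
    alpha / (number of age-tested loci).
    """
    results: dict[str, ArtifactResult] = {}
    for cnv_id, scores in score_map.items():
        res = age_intensity_scan(scores, cohort, cnv_id=cnv_id, min_blood=min_blood)
        src = source_difference_scan(scores, cohort, cnv_id=cnv_id)
        res.source_diff, res.source_p = src.source_diff, src.source_p
        res.source_tested = src.source_tested
        results[cnv_id] = res
    tested = [r for r in results.values() if r.age_tested]
    if tested:
        cut = alpha / len(tested)
        for r in tested:
            r.flagged = np.isfinite(r.age_trend_p) and r.age_trend_p < cut
    return results
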