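"""Family-based association tests on CNV intensity summaries.

The core test (FBAT-CNV) needs no discrete genotypes: for each affected
offspring it forms the deviation of the offspring's summary score from the
mid-parental average,

    d_o = y_o - (y_father + y_mother) / 2,

sums deviations within families (D_f), and tests the mean-zero null with the
family-clustered empirical variance:

    T = sum_f D_f,   V = sum_f D_f^2,   Z = T / sqrt(V),

with a two-sided P-value from the standard normal. Under Mendelian
transmission and no association, offspring deviations have mean zero
whatever the intensity-to-copy-number calibration, which is what makes the
test immune to unclusterable loci and to batch differences that are shared
within families.

Companion tests: FBAT-X (daughter-vs-mother deviations for chromosome X
against a male reference pool), a linear TDT on discrete dosage calls, and
conditional FBAT (dropping families informative at a conditioning marker).
Genome-wide utilities compute the QQ table, the over-dispersion slope of
-2 ln p against chi-square(2 df) quantiles, and the Bonferroni threshold.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssociationResult, CohortTables, GenomewideSummary, Method
from .summarize import CnvSummary

logger = logging.getLogger(__name__)

MIN_FAMILIES = 10


def family_deviations(scores: pd.Series, cohort: CohortTables) -> pd.DataFrame:
    """Per-family summed offspring-minus-midparent deviations.

    Offspring without both parents scored are excluded. Returns columns
    family_id, D (summed deviation), n_offspring.
    """
    trios = cohort.affected_trios()
    if trios.empty:
        return pd.DataFrame(columns=["family_id", "D", "n_offspring"])
    off = scores.reindex(trios["offspring"]).to_numpy()
    mid = (
        scores.reindex(trios["father"]).to_numpy()
        + scores.reindex(trios["mother"]).to_numpy()
    ) / 2.0
    d = off - mid
    ok = np.isfinite(d)
    dev = pd.DataFrame({"family_id": trios["family_id"].to_numpy()[ok], "d": d[ok]})
    grouped = dev.groupby("family_id")["d"].agg(["sum", "size"]).reset_index()
    grouped.columns = ["family_id", "D", "n_offspring"]
    return grouped


def _z_test(T: float, V: float) -> tuple[float, float]:
    if V <= 0:
        return 0.0, 1.0
    z = T / np.sqrt(V)
    return float(z), float(2.0 * stats.norm.sf(abs(z))) or np.nextafter(0, 1)


def fbat_cnv(
    scores: pd.Series,
    cohort: CohortTables,
    cnv_id: str = "",
    component_index: int = 1,
    method: Method = Method.FBAT_CNV,
) -> AssociationResult | None:
    """Intensity-based family association test on a summary component.

    Returns None when fewer than 2 usable families remain; warns below
    ``MIN_FAMILIES`` families, where the normal approximation is shaky.
    """
    dev = family_deviations(scores, cohort)
    if len(dev) < 2:
        logger.warning("fbat %s: <2 usable families, no result", cnv_id)
        return None
    if len(dev) < MIN_FAMILIES:
        logger.warning("fbat %s: only %d families, normal approximation unreliable",
                       cnv_id, len(dev))
    T = float(dev["D"].sum())
    V = float((dev["D"] ** 2).sum())
    z, p = _z_test(T, V)
    return AssociationResult(
        cnv_id=cnv_id,
        statistic=z,
        p_value=max(p, np.nextafter(0, 1)),
        n_transmissions=int(dev["n_offspring"].sum()),
        method=method,
        component_index=component_index,
    )


def fbat_x(
    scores: pd.Series,
    cohort: CohortTables,
    cnv_id: str = "",
    component_index: int = 1,
) -> AssociationResult | None:
    """Chromosome-X variant: compare affected daughters with their mothers.

    Sons and fathers are excluded (hemizygous sons are not comparable to a
    mid-parent against a male reference pool). Deviations d = y_daughter -
    y_mother are summed within families and tested as in FBAT-CNV.
    """
    s = cohort.samples
    trios = cohort.affected_trios()
    if trios.empty:
        return None
    sex = s["reported_sex"]
    daughters = trios[trios["offspring"].map(sex).eq("F").to_numpy()]
    if daughters.empty:
        logger.warning("fbat_x %s: no affected daughters with both parents", cnv_id)
        return None
    d = (
        scores.reindex(daughters["offspring"]).to_numpy()
        - scores.reindex(daughters["mother"]).to_numpy()
    )
    ok = np.isfinite(d)
    dev = pd.DataFrame(
        {"family_id": daughters["family_id"].to_numpy()[ok], "d": d[ok]}
    )
    if dev.empty or dev["family_id"].nunique() < 2:
        return None
    D = dev.groupby("family_id")["d"].sum()
    z, p = _z_test(float(D.sum()), float((D**2).sum()))
    return AssociationResult(
        cnv_id=cnv_id,
        statistic=z,
        p_value=max(p, np.nextafter(0, 1)),
        n_transmissions=int(len(dev)),
        method=Method.FBAT_X,
        component_index=component_index,
    )


def linear_tdt(
    dosage: pd.Series,
    cohort: CohortTables,
    cnv_id: str = "",
) -> AssociationResult | None:
    """Linear transmission disequilibrium test on discrete dosage calls.

    Score U = sum over affected offspring of (g_o - (g_m + g_f)/2); the null
    variance is the Mendelian transmission variance given parental
    genotypes: 1/4 per heterozygous parent per offspring (biallelic
    coding 0/1/2). Families with no heterozygous parents contribute nothing.
    """
    trios = cohort.affected_trios()
    if trios.empty:
        return None
    g_o = dosage.reindex(trios["offspring"]).to_numpy(dtype=float)
    g_f = dosage.reindex(trios["father"]).to_numpy(dtype=float)
    g_m = dosage.reindex(trios["mother"]).to_numpy(dtype=float)
    ok = np.isfinite(g_o) & np.isfinite(g_f) & np.isfinite(g_m)
    if ok.sum() == 0:
        return None
    g_o, g_f, g_m = g_o[ok], g_f[ok], g_m[ok]
    U = float(np.sum(g_o - (g_f + g_m) / 2.0))
    het = (g_f == 1).astype(float) + (g_m == 1).astype(float)
    V = float(np.sum(het) * 0.25)
    n_informative = int(np.sum(het))
    if V <= 0:
        return AssociationResult(
            cnv_id=cnv_id, statistic=0.0, p_value=1.0,
            n_transmissions=0, method=Method.LINEAR_TDT,
        )
    z, p = _z_test(U, V)
    return AssociationResult(
        cnv_id=cnv_id,
        statistic=z,
        p_value=max(p, np.nextafter(0, 1)),
        n_transmissions=n_informative,
        method=Method.LINEAR_TDT,
    )


def conditional_fbat(
    scores: pd.Series,
    cohort: CohortTables,
    conditioning_genotypes: pd.Series,
    cnv_id: str = "",
    component_index: int = 1,
) -> AssociationResult | None:
    """FBAT-CNV restricted to families uninformative at a conditioning marker.

    Families where either parent is heterozygous (dosage 1) at the
    conditioning SNP are removed; residual association at the CNV then
    cannot be driven by alleles tagged by that SNP. Returns None when no
    families remain.
    """
    s = cohort.samples
    het = conditioning_genotypes == 1
    bad_parents = set(conditioning_genotypes.index[het])
    fam_bad = set(
        s.loc[s.index.isin(bad_parents), "family_id"].unique()
    )
    keep = ~s["family_id"].isin(fam_bad)
    sub = CohortTables(samples=s[keep].copy())
    if sub.samples.empty:
        return None
    res = fbat_cnv(
        scores, sub, cnv_id=cnv_id, component_index=component_index,
        method=Method.CONDITIONAL_FBAT,
    )
    return res


def fbat_components(
    summary: CnvSummary, cohort: CohortTables
) -> list[AssociationResult]:
    """Marginal FBAT-CNV test per summary principal component."""
    out = []
    for j, col in enumerate(summary.component_scores.columns, start=1):
        res = fbat_cnv(
            summary.component_scores[col], cohort,
            cnv_id=summary.cnv_id, component_index=j,
        )
        if res is not None:
            out.append(res)
    return out


def expected_null_quantiles(n: int, df: int = 2) -> np.ndarray:
    """Medians of chi-square(df) order statistics for a sample of size n."""
    i = np.arange(1, n + 1)
    u_med = stats.beta.ppf(0.5, i, n - i + 1)
    return stats.chi2.ppf(u_med, df)


def overdispersion_slope(p_values, trim_top: float = 0.01) -> float:
    """Inflation of -2 ln p relative to its chi-square(2 df) null.

    Observed sorted -2 ln p are regressed through the origin on the
    chi-square(2) order-statistic medians after excluding the top
    ``trim_top`` fraction (potential true signals); 1.0 indicates a
    well-calibrated scan. Returns NaN with fewer than 100 P-values.
    """
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    n = p.size
    if n < 100:
        logger.warning("overdispersion_slope: need >=100 P-values, got %d", n)
        return float("nan")
    q = np.sort(-2.0 * np.log(p))
    exp = expected_null_quantiles(n, df=2)
    keep = n - int(np.ceil(trim_top * n))
    q, exp = q[:keep], exp[:keep]
    return float(np.sum(exp * q) / np.sum(exp * exp))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise alpha divided by the number of tested loci."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive number of tests")
    return alpha / m


def genomewide_summary(
    results: list[AssociationResult], alpha: float = 0.05
) -> GenomewideSummary:
    """QQ table, over-dispersion slope and Bonferroni threshold for a scan."""
    p = np.array([r.p_value for r in results], float)
    m = p.size
    if m == 0:
        raise ValueError("no results to summarize")
    q = np.sort(-2.0 * np.log(p))
    exp = expected_null_quantiles(m, df=2)
    qq = pd.DataFrame({"expected": exp, "observed": q})
    return GenomewideSummary(
        overdispersion_slope=overdispersion_slope(p),
        bonferroni_threshold=bonferroni_threshold(alpha, m),
        n_loci=m,
        qq=qq,
    )


def associate_all(
    summaries: Mapping[str, CnvSummary], cohort: CohortTables
) -> list[AssociationResult]:
    """Run FBAT-CNV on the first component of every locus summary."""
    out = []
    for cnv_id, summ in summaries.items():
        res = fbat_cnv(summ.pc1, cohort, cnv_id=cnv_id)
        if res is not None:
            out.append(res)
    return out
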