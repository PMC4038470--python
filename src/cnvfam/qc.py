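"""Sample quality control battery and the transmission-retention report.

Checks implemented: array-level noise metrics (derivative log-ratio spread),
pairwise sample-correlation swap scanning, likelihood-based parentage
consistency (Bayes factors), genome-wide heterozygosity outliers, chromosome
X dosage sex inference, tag-SNP tracking concordance (including plate-swap
recovery), and plate row/column batch scans. A transmission (affected
offspring with both parents) is retained only if all three members pass.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTables

logger = logging.getLogger(__name__)

QC_STEPS = (
    "agilent_metrics",
    "relationship",
    "correlation_swap",
    "sex_mismatch",
    "tracking",
    "heterozygosity",
)


@dataclass
class RelationshipTest:
    """Parent-offspring consistency: true-parent vs unrelated-substitute models."""

    parent_id: str
    child_id: str
    loglik_h0: float
    loglik_h1: float
    n_loci: int
    tested: bool = True

    @property
    def bayes_factor(self) -> float:
        return float(np.exp(self.loglik_h1 - self.loglik_h0))

    @property
    def flagged(self) -> bool:
        return self.tested and self.bayes_factor > 100.0


@dataclass
class QcReport:
    """Table-1-style retention accounting of transmissions through QC."""

    steps: pd.DataFrame  # rows: step, columns: blood, lcl, total, percentage
    flags: pd.DataFrame  # samples x step pass/fail booleans (True = pass)
    before: int = 0
    after: int = 0

    @property
    def retention_percentage(self) -> float:
        return retention_percentage(self.before, self.after)


def retention_percentage(before: int, after: int) -> float:
    """Percent of transmissions retained, rounded to 2 decimals."""
    if before <= 0:
        raise ValueError("before-QC transmission count must be positive")
    return round(100.0 * after / before, 2)


# ---------------------------------------------------------------------------
# array-noise metric
# ---------------------------------------------------------------------------

def dlrs(log_ratios: np.ndarray) -> float:
    """Derivative log-ratio spread of a genomically ordered probe vector.

    Robust SD (IQR / 1.349) of first differences between consecutive probes,
    divided by sqrt(2) so the metric estimates the per-probe noise SD for
    i.i.d. noise. Returns NaN with fewer than 10 finite probes.
    """
    x = np.asarray(log_ratios, float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        return float("nan")
    d = np.diff(x)
    iqr = np.subtract(*np.percentile(d, [75, 25]))
    return float(iqr / 1.349 / np.sqrt(2.0))


def dlrs_by_sample(
    normalized: pd.DataFrame, probes: pd.DataFrame, within_locus: bool = False
) -> pd.Series:
    """DLRS per sample, probes ordered by (chrom, start).

    With ``within_locus=True`` first differences are taken only between
    consecutive probes of the same CNV region and pooled — appropriate for
    a targeted array where neighbouring regions carry genuinely different
    copy-number signal that should not count as noise.
    """
    ordered = probes.sort_values(["chrom", "start"])
    ordered = ordered[ordered["probe_id"].isin(normalized.columns)]
    if not within_locus:
        block = normalized[list(ordered["probe_id"])].to_numpy()
        return pd.Series(
            [dlrs(block[i]) for i in range(block.shape[0])], index=normalized.index
        )
    diffs = []
    for _, grp in ordered.groupby("cnv_id", sort=False):
        if len(grp) < 2:
            continue
        block = normalized[list(grp["probe_id"])].to_numpy()
        diffs.append(np.diff(block, axis=1))
    if not diffs:
        return pd.Series(np.nan, index=normalized.index)
    d = np.concatenate(diffs, axis=1)
    out = np.full(d.shape[0], np.nan)
    for i in range(d.shape[0]):
        row = d[i][np.isfinite(d[i])]
        if row.size >= 9:
            iqr = np.subtract(*np.percentile(row, [75, 25]))
            out[i] = iqr / 1.349 / np.sqrt(2.0)
    return pd.Series(out, index=normalized.index)


# ---------------------------------------------------------------------------
# sample swaps
# ---------------------------------------------------------------------------

def correlation_swap_scan(
    scores: pd.DataFrame,
    whitelist: set[frozenset] | None = None,
    r2_threshold: float = 0.7,
) -> pd.DataFrame:
    """Flag unexpectedly correlated sample pairs across clusterable CNV scores.

    ``scores`` is samples x loci. All unordered pairs are scored; a pair is
    flagged when its squared Pearson correlation is >= ``r2_threshold``.
    Expected duplicates (re-runs of one individual) can be exempted.
    """
    whitelist = whitelist or set()
    X = scores.to_numpy(dtype=float)
    X = X - np.nanmean(X, axis=1, keepdims=True)
    X = np.nan_to_num(X)
    norms = np.sqrt((X**2).sum(axis=1))
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    corr = Xn @ Xn.T
    ids = list(scores.index)
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        r2 = corr[i, j] ** 2
        if r2 >= r2_threshold and frozenset((ids[i], ids[j])) not in whitelist:
            rows.append({"sample_a": ids[i], "sample_b": ids[j], "r2": float(r2)})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r2"])


# ---------------------------------------------------------------------------
# parentage
# ---------------------------------------------------------------------------

def _transmission_probs(g: int) -> np.ndarray:
    """P(transmitted allele count = 0 or 1) for parent genotype g in {0,1,2}."""
    return np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])[g]


def relationship_bayes_factor(
    child: pd.Series,
    parent: pd.Series,
    other_parent: pd.Series,
    allele_freqs: pd.Series,
    error_rate: float = 0.01,
    min_loci: int = 50,
    maf_min: float = 0.3,
    parent_id: str = "",
    child_id: str = "",
) -> RelationshipTest:
    """Bayes factor comparing non-parentage (H1) with true parentage (H0).

    Inputs are biallelic dosage calls (0/1/2, NaN missing) over clusterable
    loci and founder risk-allele frequencies. Under H0 the child's genotype
    follows Mendelian transmission from both stated parents; under H1 the
    tested parent's transmitted allele is drawn from population frequencies.
    A genotyping-error mixture on the child's observed genotype (correct
    with probability 1 - error_rate, else uniform over the other classes)
    floors the per-locus likelihood so no single Mendelian impossibility can
    veto a relationship. BF > 100 flags the pair.
    """
    freqs = allele_freqs
    usable = (
        child.notna() & parent.notna() & other_parent.notna()
        & freqs.notna() & (freqs > maf_min) & (freqs < 1 - maf_min)
    )
    idx = usable[usable].index
    if len(idx) < min_loci:
        return RelationshipTest(parent_id, child_id, 0.0, 0.0, len(idx), tested=False)

    ll0 = ll1 = 0.0
    eps = error_rate
    for locus in idx:
        gc = int(child[locus])
        gp = int(parent[locus])
        go = int(other_parent[locus])
        p = float(freqs[locus])
        tp = _transmission_probs(gp)
        to = _transmission_probs(go)
        pop = np.array([1 - p, p])
        # true child genotype distribution under each hypothesis
        true0 = np.zeros(3)
        true1 = np.zeros(3)
        for a in (0, 1):
            for b in (0, 1):
                true0[a + b] += tp[a] * to[b]
                true1[a + b] += pop[a] * to[b]
        err = np.full(3, eps / 2.0)
        err[gc] = 1.0 - eps
        ll0 += np.log(float(true0 @ err))
        ll1 += np.log(float(true1 @ err))
    return RelationshipTest(parent_id, child_id, ll0, ll1, len(idx))


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity_filter(
    calls: pd.DataFrame, het_class: int = 1
) -> pd.DataFrame:
    """Flag heterozygosity/call-rate outliers with the compound rule.

    ``calls`` is samples x autosomal clusterable loci of hard class calls
    (NaN or -1 = no call); class ``het_class`` is the heterozygote. Each
    sample's heterozygote fraction among called loci is z-scored against the
    cohort; a sample is flagged iff (z < -5 and call rate < 0.98) or
    (z > 2 and call rate < 0.92). Both branches are conjunctive: extreme
    heterozygosity alone, with a high call rate, does not flag.
    """
    X = calls.to_numpy(dtype=float)
    called = np.isfinite(X) & (X >= 0)
    call_rate = called.mean(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(
            called.sum(axis=1) > 0,
            (called & (X == het_class)).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
            np.nan,
        )
    mu, sd = np.nanmean(het), np.nanstd(het)
    z = (het - mu) / sd if sd > 0 else np.zeros_like(het)
    flagged = ((z < -5) & (call_rate < 0.98)) | ((z > 2) & (call_rate < 0.92))
    return pd.DataFrame(
        {"het_fraction": het, "z": z, "call_rate": call_rate, "flagged": flagged},
        index=calls.index,
    )


# ---------------------------------------------------------------------------
# sex inference
# ---------------------------------------------------------------------------

def infer_sex(
    chrx_scores: pd.DataFrame,
    reported_sex: pd.Series | None = None,
    min_separation: float = 0.5,
    fallback_threshold: float = 0.5,
) -> pd.DataFrame:
    """Infer sex from mean chromosome-X log2 ratios against a male reference.

    With a one-X-copy male reference pool, males sit near log2 ratio 0 and
    females near +1. A two-means split is used; if the cluster centers are
    closer than ``min_separation`` (e.g. a single-sex cohort) the fixed
    threshold ``fallback_threshold`` is used instead.
    """
    mean_x = chrx_scores.mean(axis=1, skipna=True)
    x = mean_x.to_numpy(dtype=float)
    ok = np.isfinite(x)
    inferred = np.array(["unknown"] * len(x), dtype=object)
    if ok.sum() >= 2:
        c_lo, c_hi = _two_means_1d(x[ok])
        if abs(c_hi - c_lo) < min_separation:
            female = x >= fallback_threshold
        else:
            female = np.abs(x - c_hi) < np.abs(x - c_lo)
            # orient: the higher cluster is female only if it sits near +1
            if c_hi < fallback_threshold:
                female = np.zeros_like(female, dtype=bool)
    elif ok.sum() == 1:
        female = x >= fallback_threshold
    else:
        female = np.zeros(len(x), dtype=bool)
    inferred[ok] = np.where(female[ok], "F", "M")
    out = pd.DataFrame({"mean_x_ratio": mean_x, "inferred_sex": inferred},
                       index=chrx_scores.index)
    if reported_sex is not None:
        rep = reported_sex.reindex(chrx_scores.index)
        out["reported_sex"] = rep
        out["mismatch"] = (
            rep.notna() & (rep != "unknown") & (out["inferred_sex"] != "unknown")
            & (rep != out["inferred_sex"])
        )
    return out


def _two_means_1d(x: np.ndarray, n_iter: int = 50) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return lo, hi
    c = np.array([lo, hi])
    for _ in range(n_iter):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == k].mean() if (assign == k).any() else c[k] for k in (0, 1)
        ])
        if np.allclose(new, c):
            break
        c = new
    return float(min(c)), float(max(c))


# ---------------------------------------------------------------------------
# tracking concordance
# ---------------------------------------------------------------------------

def tracking_concordance(
    mapped_calls: pd.DataFrame,
    expected: pd.DataFrame,
    min_loci: int = 20,
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Per-sample concordance of CNV-derived classes with external tag genotypes.

    ``mapped_calls`` and ``expected`` are samples x loci on a shared coding
    (NaN = missing). Samples with fewer than ``min_loci`` jointly called loci
    are untested; below ``threshold`` concordance is flagged.
    """
    loci = [c for c in mapped_calls.columns if c in expected.columns]
    a = mapped_calls[loci].to_numpy(dtype=float)
    b = expected.reindex(mapped_calls.index)[loci].to_numpy(dtype=float)
    both = np.isfinite(a) & np.isfinite(b)
    n = both.sum(axis=1)
    agree = ((a == b) & both).sum(axis=1)
    with np.errstate(invalid="ignore"):
        conc = np.where(n > 0, agree / np.maximum(n, 1), np.nan)
    tested = n >= min_loci
    return pd.DataFrame(
        {
            "concordance": np.where(tested, conc, np.nan),
            "n_loci": n,
            "tested": tested,
            "flagged": tested & (conc < threshold),
        },
        index=mapped_calls.index,
    )


def cross_plate_concordance(
    mapped_calls: pd.DataFrame,
    expected: pd.DataFrame,
    cohort: CohortTables,
) -> pd.DataFrame:
    """Concordance of each plate's calls against each plate's expectations.

    Samples are matched by well position; the diagonal should dominate. A
    full plate swap shows up as an off-diagonal pair (i, j), (j, i)
    exceeding both diagonals, which is how a swapped pair is recovered.
    """
    meta = cohort.samples.reindex(mapped_calls.index)
    plates = sorted(meta["plate_id"].dropna().unique())
    loci = [c for c in mapped_calls.columns if c in expected.columns]
    by_well: dict[str, dict[tuple, str]] = {
        p: {} for p in plates
    }
    for sid, row in meta.iterrows():
        by_well[row["plate_id"]][(row["well_row"], row["well_col"])] = sid
    M = pd.DataFrame(np.nan, index=plates, columns=plates)
    for pi in plates:
        for pj in plates:
            wells = set(by_well[pi]) & set(by_well[pj])
            if not wells:
                continue
            tot = agree = 0
            for w in wells:
                a = mapped_calls.loc[by_well[pi][w], loci].to_numpy(dtype=float)
                b = expected.loc[by_well[pj][w], loci].to_numpy(dtype=float)
                both = np.isfinite(a) & np.isfinite(b)
                tot += int(both.sum())
                agree += int(((a == b) & both).sum())
            if tot:
                M.loc[pi, pj] = agree / tot
    return M


# ---------------------------------------------------------------------------
# plate batch effects
# ---------------------------------------------------------------------------

def plate_effect_scan(
    R: pd.DataFrame, cohort: CohortTables
) -> dict[str, object]:
    """Kruskal-Wallis tests of per-sample median raw test-channel intensity
    across plate rows and across plate columns."""
    meta = cohort.samples.reindex(R.index)
    med = R.median(axis=1)
    out: dict[str, object] = {}
    for axis, col in (("row", "well_row"), ("col", "well_col")):
        groups = [
            med[meta[col] == g].dropna().to_numpy()
            for g in sorted(meta[col].dropna().unique())
        ]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            out[f"p_{axis}"] = float("nan")
            out[f"{axis}_tested"] = False
            continue
        stat, p = stats.kruskal(*groups)
        out[f"p_{axis}"] = float(p)
        out[f"{axis}_tested"] = True
        out[f"{axis}_medians"] = pd.Series(
            {g: float(np.median(med[meta[col] == g].dropna()))
             for g in sorted(meta[col].dropna().unique())}
        )
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def qc_report(flags: pd.DataFrame, cohort: CohortTables) -> QcReport:
    """Retention of transmissions through each QC step and overall.

    ``flags`` is samples x step booleans, True = pass (missing samples or
    steps default to pass). Each step's row counts transmissions retained
    applying that step alone; the final row applies all steps jointly. A
    transmission is retained iff offspring and both parents pass.
    """
    base = CohortTables(samples=cohort.samples.copy())
    base.samples["qc_pass"] = True
    trios = base.affected_trios()
    before = len(trios)
    src = cohort.samples["dna_source"]

    def count(passing: pd.Series) -> tuple[int, int, int]:
        ok = (
            passing.reindex(trios["offspring"]).fillna(True).to_numpy()
            & passing.reindex(trios["father"]).fillna(True).to_numpy()
            & passing.reindex(trios["mother"]).fillna(True).to_numpy()
        )
        blood = int((ok & (src.reindex(trios["offspring"]).to_numpy() == "blood")).sum())
        lcl = int((ok & (src.reindex(trios["offspring"]).to_numpy() == "lcl")).sum())
        return blood, lcl, int(ok.sum())

    rows = []
    b, l, t = count(pd.Series(True, index=cohort.samples.index))
    rows.append({"step": "before_qc", "blood": b, "lcl": l, "total": t,
                 "percentage": 100.0})
    all_pass = pd.Series(True, index=cohort.samples.index)
    for step in flags.columns:
        passing = flags[step].reindex(cohort.samples.index).fillna(True).astype(bool)
        b, l, t = count(passing)
        rows.append({"step": step, "blood": b, "lcl": l, "total": t,
                     "percentage": retention_percentage(before, t) if before else np.nan})
        all_pass &= passing
    b, l, t = count(all_pass)
    rows.append({"step": "after_qc", "blood": b, "lcl": l, "total": t,
                 "percentage": retention_percentage(before, t) if before else np.nan})
    steps = pd.DataFrame(rows).set_index("step")
    return QcReport(steps=steps, flags=flags, before=before, after=t)


def apply_qc(cohort: CohortTables, flags: pd.DataFrame) -> CohortTables:
    """Return a cohort with ``qc_pass`` set to the conjunction of all flags."""
    all_pass = pd.Series(True, index=cohort.samples.index)
    for step in flags.columns:
        all_pass &= flags[step].reindex(cohort.samples.index).fillna(True).astype(bool)
    out = CohortTables(samples=cohort.samples.copy())
    out.samples["qc_pass"] = all_pass.to_numpy()
    return out
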