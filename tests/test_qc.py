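import numpy as np
import pandas as pd
import pytest

from cnvfam import (
    CohortTables,
    correlation_swap_scan,
    dlrs,
    heterozygosity_filter,
    infer_sex,
    normalize,
    plate_effect_scan,
    qc_report,
    relationship_bayes_factor,
    retention_percentage,
    tracking_concordance,
)
from cnvfam.qc import apply_qc, cross_plate_concordance

from conftest import make_trio_cohort


class TestDlrs:
    def test_constant_log_ratio_is_zero(self):
        assert dlrs(np.full(100, 0.3)) == 0.0

    def test_iid_gaussian_recovers_sigma(self):
        rng = np.random.default_rng(0)
        sigma = 0.25
        est = dlrs(rng.normal(0, sigma, 10_000))
        assert est == pytest.approx(sigma, rel=0.05)

    def test_robust_to_single_outlier(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.2, 1000)
        clean = dlrs(x)
        x[500] = 50.0
        assert dlrs(x) == pytest.approx(clean, rel=0.10)

    def test_too_few_probes_missing(self):
        assert np.isnan(dlrs(np.arange(5, dtype=float)))


class TestCorrelationSwapScan:
    def _scores(self, n_samples=40, n_loci=452, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=(n_samples, n_loci)).astype(float)
        g += rng.normal(0, 0.2, g.shape)
        return pd.DataFrame(g, index=[f"s{i}" for i in range(n_samples)])

    def test_duplicated_sample_flagged_with_r2_one(self):
        scores = self._scores()
        scores.loc["s1"] = scores.loc["s0"]
        flagged = correlation_swap_scan(scores)
        pair = flagged[(flagged.sample_a == "s0") & (flagged.sample_b == "s1")]
        assert len(pair) == 1
        assert pair["r2"].iloc[0] == pytest.approx(1.0)

    def test_unrelated_samples_rarely_flagged(self):
        flagged = correlation_swap_scan(self._scores(seed=2))
        n_pairs = 40 * 39 // 2
        assert len(flagged) <= 0.01 * n_pairs

    def test_whitelisted_duplicates_exempt(self):
        scores = self._scores(seed=3)
        scores.loc["s1"] = scores.loc["s0"]
        flagged = correlation_swap_scan(scores, whitelist={frozenset(("s0", "s1"))})
        assert flagged.empty

    def test_parent_child_pairs_below_cutoff(self):
        # shared-allele correlation ~0.5 (r^2 ~ 0.25) stays under 0.7
        rng = np.random.default_rng(4)
        n_loci = 452
        parents = rng.binomial(2, 0.4, size=(20, n_loci)).astype(float)
        kids = np.zeros_like(parents)
        for i in range(20):
            other = rng.binomial(2, 0.4, n_loci)
            kids[i] = (
                rng.binomial(1, parents[i] / 2.0) + rng.binomial(1, other / 2.0)
            )
        scores = pd.DataFrame(
            np.vstack([parents, kids]) + rng.normal(0, 0.1, (40, n_loci)),
            index=[f"p{i}" for i in range(20)] + [f"k{i}" for i in range(20)],
        )
        flagged = correlation_swap_scan(scores)
        assert flagged.empty


class TestRelationshipBayesFactor:
    @staticmethod
    def _simulate_trios(n_trios, n_loci=318, seed=0, error=0.01):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.3, 0.5, n_loci)
        fathers = rng.binomial(2, freqs, size=(n_trios, n_loci))
        mothers = rng.binomial(2, freqs, size=(n_trios, n_loci))
        strangers = rng.binomial(2, freqs, size=(n_trios, n_loci))
        kids = (
            rng.binomial(1, fathers / 2.0) + rng.binomial(1, mothers / 2.0)
        )

        def observe(g):
            flip = rng.random(g.shape) < error
            noise = rng.integers(0, 3, g.shape)
            return np.where(flip, noise, g).astype(float)

        return (freqs, observe(fathers), observe(mothers), observe(kids),
                observe(strangers))

    def test_true_parents_rarely_flagged(self):
        freqs, fa, mo, kid, _ = self._simulate_trios(150, seed=1)
        fs = pd.Series(freqs)
        flagged = sum(
            relationship_bayes_factor(
                pd.Series(kid[i]), pd.Series(fa[i]), pd.Series(mo[i]), fs
            ).flagged
            for i in range(150)
        )
        assert flagged <= 1  # < 1%

    def test_substituted_parent_flagged(self):
        freqs, fa, mo, kid, stranger = self._simulate_trios(150, seed=2)
        fs = pd.Series(freqs)
        flagged = sum(
            relationship_bayes_factor(
                pd.Series(kid[i]), pd.Series(stranger[i]), pd.Series(mo[i]), fs
            ).flagged
            for i in range(150)
        )
        assert flagged >= 143  # > 95%

    def test_mendelian_impossibility_raises_bf_not_infinite(self):
        n = 60
        freqs = pd.Series(np.full(n, 0.4))
        fa = pd.Series(np.zeros(n))
        mo = pd.Series(np.zeros(n))
        kid = pd.Series(np.zeros(n))
        kid.iloc[0] = 2.0  # impossible from two 0/0 parents
        base = relationship_bayes_factor(kid * 0, fa, mo, freqs)
        with_err = relationship_bayes_factor(kid, fa, mo, freqs)
        assert np.isfinite(with_err.loglik_h0)
        assert with_err.bayes_factor > base.bayes_factor

    def test_too_few_loci_untested(self):
        freqs = pd.Series(np.full(10, 0.4))
        g = pd.Series(np.ones(10))
        res = relationship_bayes_factor(g, g, g, freqs)
        assert not res.tested and not res.flagged


class TestHeterozygosityFilter:
    def _calls(self, n=200, n_loci=310, seed=0):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0.0, 1.0, 2.0], p=[0.25, 0.5, 0.25], size=(n, n_loci))
        return pd.DataFrame(calls, index=[f"s{i}" for i in range(n)])

    def test_low_het_low_call_rate_flagged(self):
        calls = self._calls()
        calls.loc["s0"] = 0.0  # no heterozygotes: extreme negative z
        calls.loc["s0", calls.columns[:10]] = np.nan  # call rate ~96.8%
        out = heterozygosity_filter(calls)
        assert out.loc["s0", "z"] < -5
        assert out.loc["s0", "flagged"]

    def test_low_het_but_high_call_rate_passes(self):
        calls = self._calls(seed=1)
        calls.loc["s0"] = 0.0  # z << -5 but call rate 100%
        out = heterozygosity_filter(calls)
        assert out.loc["s0", "z"] < -5
        assert not out.loc["s0", "flagged"]

    def test_high_het_low_call_rate_flagged(self):
        calls = self._calls(seed=2)
        calls.loc["s0"] = 1.0  # all het: z > 2
        calls.loc["s0", calls.columns[:30]] = np.nan  # call rate ~90%
        out = heterozygosity_filter(calls)
        assert out.loc["s0", "z"] > 2
        assert out.loc["s0", "flagged"]


class TestInferSex:
    def test_simulated_cohort_sexes_recovered(self, base_sim):
        sim = base_sim
        normed = normalize(sim.intensity, 1).normalized_frame()
        xprobes = [p for p in sim.intensity.probe_ids if p.startswith("XCTRL")]
        out = infer_sex(normed[xprobes], sim.cohort.samples["reported_sex"])
        assert int(out["mismatch"].sum()) == 0
        females = out["inferred_sex"] == "F"
        assert out.loc[females, "mean_x_ratio"].mean() == pytest.approx(1.0, abs=0.2)
        assert out.loc[~females, "mean_x_ratio"].mean() == pytest.approx(0.0, abs=0.2)

    def test_single_sex_cohort_uses_threshold_fallback(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.normal(0.0, 0.05, size=(30, 5)),
                              index=[f"s{i}" for i in range(30)])
        out = infer_sex(scores)
        assert (out["inferred_sex"] == "M").all()


class TestTrackingConcordance:
    def _calls(self, n=30, n_loci=40, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=(n, n_loci)).astype(float)
        return pd.DataFrame(g, index=[f"s{i}" for i in range(n)])

    def test_identical_calls_pass(self):
        calls = self._calls()
        out = tracking_concordance(calls, calls.copy())
        assert (out["concordance"] == 1.0).all()
        assert not out["flagged"].any()

    def test_independent_genotypes_flagged(self):
        calls = self._calls(seed=1)
        other = self._calls(seed=2)
        out = tracking_concordance(calls, other)
        # expected match rate sum_g f_g^2 at p=0.3 is ~0.41, far below 0.8
        assert out["flagged"].all()
        assert out["concordance"].mean() == pytest.approx(0.41, abs=0.1)

    def test_too_few_loci_untested(self):
        calls = self._calls(n_loci=10)
        out = tracking_concordance(calls, calls.copy())
        assert not out["tested"].any()
        assert not out["flagged"].any()

    def test_full_plate_swap_recovered(self):
        rng = np.random.default_rng(3)
        n_per_plate, n_loci = 12, 40
        rows = []
        expected = {}
        for plate in ("P1", "P2", "P3"):
            for w in range(n_per_plate):
                sid = f"{plate}_s{w}"
                expected[sid] = rng.binomial(2, 0.3, n_loci).astype(float)
                rows.append(dict(sample_id=sid, family_id=sid, father_id=None,
                                 mother_id=None, reported_sex="M", affected=False,
                                 age_at_sampling=30.0, dna_source="blood",
                                 plate_id=plate, well_row="A", well_col=w + 1))
        cohort = CohortTables(samples=pd.DataFrame(rows).set_index("sample_id"))
        exp_df = pd.DataFrame(expected).T
        calls = exp_df.copy()
        # swap plates P1 and P2 wholesale
        for w in range(n_per_plate):
            calls.loc[f"P1_s{w}"] = exp_df.loc[f"P2_s{w}"]
            calls.loc[f"P2_s{w}"] = exp_df.loc[f"P1_s{w}"]
        per_sample = tracking_concordance(calls, exp_df)
        swapped = [s for s in per_sample.index if not s.startswith("P3")]
        assert per_sample.loc[swapped, "flagged"].all()
        M = cross_plate_concordance(calls, exp_df, cohort)
        assert M.loc["P1", "P2"] == pytest.approx(1.0)
        assert M.loc["P2", "P1"] == pytest.approx(1.0)
        assert M.loc["P3", "P3"] == pytest.approx(1.0)
        assert M.loc["P1", "P1"] < 0.8


class TestPlateEffectScan:
    def _setup(self, shift_row=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        data = {}
        sid = 0
        for r in "ABCD":
            for c in range(1, 7):
                for _ in range(3):
                    s = f"s{sid}"
                    sid += 1
                    x = rng.normal(1000, 50, 30)
                    if shift_row == r:
                        x *= 1.3
                    data[s] = x
                    rows.append(dict(sample_id=s, family_id=s, father_id=None,
                                     mother_id=None, reported_sex="M",
                                     affected=False, age_at_sampling=30.0,
                                     dna_source="blood", plate_id="P1",
                                     well_row=r, well_col=c))
        cohort = CohortTables(samples=pd.DataFrame(rows).set_index("sample_id"))
        return pd.DataFrame(data).T, cohort

    def test_homogeneous_plate_not_significant(self):
        R, cohort = self._setup()
        out = plate_effect_scan(R, cohort)
        assert out["row_tested"] and out["col_tested"]
        assert out["p_row"] > 1e-3

    def test_shifted_row_detected(self):
        R, cohort = self._setup(shift_row="B", seed=1)
        out = plate_effect_scan(R, cohort)
        assert out["p_row"] < 0.01

    def test_single_row_untested(self):
        R, cohort = self._setup()
        cohort.samples["well_row"] = "A"
        out = plate_effect_scan(R, cohort)
        assert not out["row_tested"]
        assert np.isnan(out["p_row"])


class TestQcReport:
    def test_paper_scale_retention_arithmetic(self):
        assert retention_percentage(3856, 3630) == 94.14

    def test_no_failures_give_100_percent(self):
        cohort = make_trio_cohort(20)
        flags = pd.DataFrame({"any": True}, index=cohort.samples.index)
        report = qc_report(flags, cohort)
        assert report.retention_percentage == 100.00

    def test_failed_parent_removes_family_transmissions(self):
        cohort = make_trio_cohort(10, n_offspring=2)
        flags = pd.DataFrame({"check": True}, index=cohort.samples.index)
        flags.loc["F00000_fa", "check"] = False
        report = qc_report(flags, cohort)
        assert report.before == 20
        assert report.after == 18

    def test_retention_monotone_as_steps_accumulate(self):
        cohort = make_trio_cohort(30)
        rng = np.random.default_rng(5)
        flags = pd.DataFrame(
            rng.random((len(cohort.samples), 3)) > 0.05,
            index=cohort.samples.index, columns=["a", "b", "c"],
        )
        counts = []
        for j in range(1, 4):
            counts.append(qc_report(flags.iloc[:, :j], cohort).after)
        assert counts == sorted(counts, reverse=True)

    def test_apply_qc_restricts_transmissions(self):
        cohort = make_trio_cohort(10)
        flags = pd.DataFrame({"check": True}, index=cohort.samples.index)
        flags.loc["F00001_o0", "check"] = False
        filtered = apply_qc(cohort, flags)
        assert filtered.transmission_count() == cohort.transmission_count() - 1


class TestDlrsBySample:
    def test_within_locus_mode_ignores_between_locus_signal_jumps(self):
        from cnvfam.qc import dlrs_by_sample

        rng = np.random.default_rng(0)
        sigma = 0.1
        probes = []
        cols = {}
        for l in range(20):
            level = rng.uniform(-2, 2)  # genuine copy-number signal per locus
            for j in range(5):
                pid = f"L{l}_p{j}"
                probes.append({"probe_id": pid, "chrom": "chr1",
                               "start": 10_000 * l + 100 * j,
                               "end": 10_000 * l + 100 * j + 60,
                               "cnv_id": f"L{l}"})
                cols[pid] = level + rng.normal(0, sigma, 4)
        normed = pd.DataFrame(cols, index=[f"s{i}" for i in range(4)])
        probes = pd.DataFrame(probes)
        within = dlrs_by_sample(normed, probes, within_locus=True)
        across = dlrs_by_sample(normed, probes)
        assert within.mean() == pytest.approx(sigma, rel=0.35)
        assert (across > within).all()  # locus jumps inflate the naive metric
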