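import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvfam import (
    CohortTables,
    bonferroni_threshold,
    conditional_fbat,
    family_deviations,
    fbat_cnv,
    fbat_components,
    fbat_x,
    linear_tdt,
    overdispersion_slope,
)
from cnvfam.associate import expected_null_quantiles, genomewide_summary
from cnvfam.simulate import sample_affected_trio_genotypes
from cnvfam.summarize import CnvSummary

from conftest import make_trio_cohort


def null_scores(cohort, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0, scale, len(cohort.samples)),
                     index=cohort.samples.index)


def dosage_scores(cohort, p=0.4, psi=1.0, seed=0, noise=0.0):
    """Summary scores equal to (noisy) true dosage under the disease model."""
    rng = np.random.default_rng(seed)
    trios = cohort.affected_trios()
    gf, gm, gc = sample_affected_trio_genotypes(len(trios), p, psi, rng)
    scores = pd.Series(np.nan, index=cohort.samples.index)
    scores[trios["father"].to_numpy()] = gf
    scores[trios["mother"].to_numpy()] = gm
    scores[trios["offspring"].to_numpy()] = gc
    if noise:
        scores += rng.normal(0, noise, len(scores))
    return scores


class TestFbatCnv:
    def test_offspring_equal_midparent_gives_null(self):
        cohort = make_trio_cohort(50)
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=len(cohort.samples)),
                           index=cohort.samples.index)
        trios = cohort.affected_trios()
        scores[trios["offspring"].to_numpy()] = (
            scores[trios["father"]].to_numpy() + scores[trios["mother"]].to_numpy()
        ) / 2
        res = fbat_cnv(scores, cohort, cnv_id="L")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_distorted_locus_detected(self):
        cohort = make_trio_cohort(250, n_offspring=2)
        hits = 0
        for rep in range(10):
            scores = dosage_scores(cohort, psi=2.0, seed=rep, noise=0.1)
            res = fbat_cnv(scores, cohort, cnv_id="L")
            if res.p_value < 1e-4:
                hits += 1
        assert hits >= 9

    def test_invariant_to_per_family_constant(self):
        cohort = make_trio_cohort(40)
        scores = null_scores(cohort, seed=2)
        res_a = fbat_cnv(scores, cohort, cnv_id="L")
        shifts = {f: i * 1.7 - 3 for i, f in
                  enumerate(cohort.samples["family_id"].unique())}
        shifted = scores + cohort.samples["family_id"].map(shifts)
        res_b = fbat_cnv(shifted, cohort, cnv_id="L")
        assert res_b.statistic == pytest.approx(res_a.statistic, abs=1e-9)
        assert res_b.p_value == pytest.approx(res_a.p_value, abs=1e-12)

    def test_invariant_to_global_affine_rescale(self):
        cohort = make_trio_cohort(40)
        scores = null_scores(cohort, seed=3)
        res_a = fbat_cnv(scores, cohort, cnv_id="L")
        res_b = fbat_cnv(scores * 7.3 + 11.0, cohort, cnv_id="L")
        assert res_b.statistic == pytest.approx(res_a.statistic, abs=1e-9)

    def test_sign_flip_flips_z_keeps_p(self):
        cohort = make_trio_cohort(40)
        scores = null_scores(cohort, seed=4)
        res_a = fbat_cnv(scores, cohort, cnv_id="L")
        res_b = fbat_cnv(-scores, cohort, cnv_id="L")
        assert res_b.statistic == pytest.approx(-res_a.statistic)
        assert res_b.p_value == pytest.approx(res_a.p_value)

    def test_transmissions_counted(self):
        cohort = make_trio_cohort(30, n_offspring=2)
        res = fbat_cnv(null_scores(cohort, seed=5), cohort, cnv_id="L")
        assert res.n_transmissions == 60

    def test_too_few_families_returns_none(self):
        cohort = make_trio_cohort(1)
        assert fbat_cnv(null_scores(cohort), cohort, cnv_id="L") is None


class TestFbatX:
    def test_daughters_equal_mothers_null(self):
        cohort = make_trio_cohort(60)
        scores = null_scores(cohort, seed=6)
        trios = cohort.affected_trios()
        sex = cohort.samples["reported_sex"]
        for _, row in trios.iterrows():
            if sex[row["offspring"]] == "F":
                scores[row["offspring"]] = scores[row["mother"]]
        res = fbat_x(scores, cohort, cnv_id="X")
        assert res.p_value == 1.0

    def test_all_son_families_untestable(self):
        cohort = make_trio_cohort(20)
        cohort.samples.loc[cohort.samples["affected"], "reported_sex"] = "M"
        assert fbat_x(null_scores(cohort), cohort, cnv_id="X") is None

    def test_null_calibration(self):
        cohort = make_trio_cohort(200)
        pvals = [fbat_x(null_scores(cohort, seed=s), cohort, cnv_id="X").p_value
                 for s in range(300)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLinearTdt:
    def test_all_homozygous_parents_give_p_one(self):
        cohort = make_trio_cohort(30)
        dosage = pd.Series(2.0, index=cohort.samples.index)
        res = linear_tdt(dosage, cohort, cnv_id="L")
        assert res.p_value == 1.0
        assert res.n_transmissions == 0

    def test_matches_mcnemar_tdt_chi_square(self):
        cohort = make_trio_cohort(500, n_offspring=1)
        dosage = dosage_scores(cohort, p=0.4, psi=1.5, seed=7)
        res = linear_tdt(dosage, cohort, cnv_id="L")
        # classic TDT: (b - c)^2 / (b + c) over het-parent transmissions
        trios = cohort.affected_trios()
        gf = dosage[trios["father"]].to_numpy()
        gm = dosage[trios["mother"]].to_numpy()
        gc = dosage[trios["offspring"]].to_numpy()
        n_het = (gf == 1).astype(int) + (gm == 1).astype(int)
        hom_risk = (gf == 2).astype(int) + (gm == 2).astype(int)
        b = int((gc - hom_risk)[n_het > 0].sum())  # risk transmissions via het
        n = int(n_het.sum())
        c = n - b
        mcnemar = (b - c) ** 2 / (b + c)
        assert res.statistic**2 == pytest.approx(mcnemar, rel=0.10)

    def test_null_calibration(self):
        cohort = make_trio_cohort(300)
        pvals = []
        for s in range(200):
            res = linear_tdt(dosage_scores(cohort, psi=1.0, seed=s + 1), cohort)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestConditionalFbat:
    def test_all_parents_heterozygous_leaves_nothing(self):
        cohort = make_trio_cohort(20)
        scores = null_scores(cohort)
        parents = cohort.samples.index[~cohort.samples["affected"]]
        tag = pd.Series(1.0, index=parents)
        assert conditional_fbat(scores, cohort, tag, cnv_id="L") is None

    def test_signal_from_tag_removed_by_conditioning(self):
        # association driven entirely by the tagged allele: conditioning on
        # tag-uninformative families leaves a null test
        cohort = make_trio_cohort(400)
        pvals = []
        for rep in range(25):
            scores = dosage_scores(cohort, p=0.4, psi=2.0, seed=rep, noise=0.05)
            tag = scores.round().clip(0, 2)[~cohort.samples["affected"]]
            res = conditional_fbat(scores, cohort, tag, cnv_id="L")
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_independent_secondary_signal_retains_power(self):
        cohort = make_trio_cohort(300)
        hits = 0
        for rep in range(10):
            primary = dosage_scores(cohort, p=0.4, psi=1.0, seed=rep)
            secondary = dosage_scores(cohort, p=0.4, psi=3.0, seed=1000 + rep)
            scores = secondary + np.random.default_rng(rep).normal(
                0, 0.05, len(secondary))
            tag = primary[~cohort.samples["affected"]]
            res = conditional_fbat(pd.Series(scores, index=primary.index),
                                   cohort, tag, cnv_id="L")
            if res is not None and res.p_value < 0.01:
                hits += 1
        assert hits >= 8


class TestComponents:
    def test_single_component_matches_fbat_cnv(self):
        cohort = make_trio_cohort(40)
        scores = null_scores(cohort, seed=8)
        summ = CnvSummary(
            cnv_id="L",
            component_scores=pd.DataFrame({"PC1": scores}),
            loadings=pd.DataFrame({"PC1": [1.0]}, index=["p1"]),
        )
        results = fbat_components(summ, cohort)
        direct = fbat_cnv(scores, cohort, cnv_id="L")
        assert len(results) == 1
        assert results[0].statistic == pytest.approx(direct.statistic)
        assert results[0].component_index == 1


class TestGenomewide:
    def test_slope_one_at_exact_null_order_statistic_medians(self):
        exp = expected_null_quantiles(500, df=2)
        p = np.exp(-exp / 2.0)  # invert -2 ln p
        assert overdispersion_slope(p) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_p_slope_near_one(self):
        slopes = [
            overdispersion_slope(np.random.default_rng(s).uniform(size=3000))
            for s in range(5)
        ]
        for s in slopes:
            assert s == pytest.approx(1.0, abs=0.05)

    def test_deflated_p_inflates_slope(self):
        p = np.random.default_rng(0).uniform(size=2000)
        assert overdispersion_slope(p**2) > overdispersion_slope(p)

    def test_too_few_p_missing(self):
        assert np.isnan(overdispersion_slope(np.full(50, 0.5)))

    def test_bonferroni_values_and_errors(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 3410) == pytest.approx(1.466e-5, rel=1e-3)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)

    def test_genomewide_summary_shape(self):
        cohort = make_trio_cohort(40)
        results = []
        for s in range(120):
            r = fbat_cnv(null_scores(cohort, seed=s), cohort, cnv_id=f"L{s}")
            results.append(r)
        summ = genomewide_summary(results)
        assert summ.n_loci == 120
        assert summ.bonferroni_threshold == pytest.approx(0.05 / 120)
        assert summ.qq.shape == (120, 2)
        assert summ.overdispersion_slope > 0
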