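"""RAi / β-factor machinery, nonparametric significance, variant comparisons."""

import numpy as np
import pytest

import lumibias as lb
from lumibias.bias_stats import (
    BiasResult,
    compare_variants,
    compute_beta,
    compute_rai,
    dunn_vs_control,
    kruskal_wallis,
    summarize_bias,
)
from lumibias.bias_stats import test_bias_significance as fill_significance
from lumibias.dose_response import LogisticFit
from lumibias.published import (
    S159A_FUNCTIONAL_DATA,
    WT_FUNCTIONAL_DATA,
    beta_from_published,
    fit_from_values,
)
from lumibias.synthetic_data import NoiseModel
from lumibias.types import PATHWAY_ARR, PATHWAY_GQ

import oracles
from conftest import make_spec


def fit(ec50_nM, emax):
    return fit_from_values(ec50_nM, emax)


class TestRAi:
    def test_self_reference_is_one(self):
        f = fit(12.9, 99.7)
        assert compute_rai(f, f).value == pytest.approx(1.0)

    def test_published_4a_arr2_value(self):
        """RAi of the strongly biased 4-bromo analogue in the βarr2 assay,
        against direct hand arithmetic on the published cells."""
        rai = compute_rai(fit(11.1, 112.0), fit(12.9, 99.7))
        assert rai.value == pytest.approx((112.0 * 12.9) / (99.7 * 11.1), rel=1e-12)
        assert rai.value == pytest.approx(1.306, abs=5e-4)

    def test_common_emax_rescale_invariance(self):
        a = compute_rai(fit(11.1, 112.0), fit(12.9, 99.7))
        b = compute_rai(fit(11.1, 224.0), fit(12.9, 199.4))
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_nd_fit_gives_nd_rai(self):
        assert not compute_rai(LogisticFit.nd("x"), fit(1, 100)).ok


class TestBeta:
    def test_equal_rai_gives_zero(self):
        a = compute_rai(fit(10, 100), fit(10, 100), "C", PATHWAY_ARR, "R")
        g = compute_rai(fit(20, 50), fit(20, 50), "C", PATHWAY_GQ, "R")
        assert compute_beta(a, g) == pytest.approx(0.0)

    def test_published_4a_combined_beta(self):
        """β of 4a from the published combined values matches the printed
        β-factor ≈ 1.24 (hand arithmetic:
        log10((112·12.9/(99.7·11.1))/(28·13.2/(100·48.8)))."""
        expected = np.log10(
            (112.0 * 12.9 / (99.7 * 11.1)) / (28.0 * 13.2 / (100.0 * 48.8))
        )
        beta = beta_from_published("4a")
        assert beta == pytest.approx(expected, rel=1e-12)
        assert beta == pytest.approx(1.240, rel=0.01)

    def test_antisymmetry_under_pathway_swap(self):
        a = compute_rai(fit(11.1, 112), fit(12.9, 99.7), "C", PATHWAY_ARR, "R")
        g = compute_rai(fit(48.8, 28), fit(13.2, 100), "C", PATHWAY_GQ, "R")
        assert compute_beta(a, g) == pytest.approx(-compute_beta(g, a))

    def test_nd_propagates(self):
        a = compute_rai(LogisticFit.nd("weak"), fit(1, 100), "C", PATHWAY_ARR, "R")
        g = compute_rai(fit(1, 100), fit(1, 100), "C", PATHWAY_GQ, "R")
        assert compute_beta(a, g) is None

    def test_mismatched_compounds_rejected(self):
        a = compute_rai(fit(1, 100), fit(1, 100), "C1", PATHWAY_ARR, "R")
        g = compute_rai(fit(1, 100), fit(1, 100), "C2", PATHWAY_GQ, "R")
        with pytest.raises(ValueError, match="share compound"):
            compute_beta(a, g)

    def test_response_axis_rescale_invariance(self):
        """β is unchanged if the normalized response axis is rescaled by a
        common factor (normalization-convention independence)."""
        k = 2.5
        b1 = compute_beta(
            compute_rai(fit(11.1, 112), fit(12.9, 99.7), "C", PATHWAY_ARR, "R"),
            compute_rai(fit(48.8, 28), fit(13.2, 100), "C", PATHWAY_GQ, "R"),
        )
        b2 = compute_beta(
            compute_rai(fit(11.1, 112 * k), fit(12.9, 99.7 * k), "C", PATHWAY_ARR, "R"),
            compute_rai(fit(48.8, 28 * k), fit(13.2, 100 * k), "C", PATHWAY_GQ, "R"),
        )
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_reference_switch_shifts_all_betas_by_constant(self):
        """Changing the reference agonist shifts every compound's β by the
        same constant (difference-of-logs identity), exactly."""
        compounds = {c: WT_FUNCTIONAL_DATA[c] for c in ("4a", "6a", "6e", "5-HT")}
        beta_vs_lsd = {c: beta_from_published(c, reference="LSD") for c in compounds}
        beta_vs_5ht = {c: beta_from_published(c, reference="5-HT") for c in compounds}
        shifts = [beta_vs_lsd[c] - beta_vs_5ht[c] for c in compounds]
        assert np.ptp(shifts) == pytest.approx(0.0, abs=1e-12)


class TestSummarizeBias:
    def _study_bias(self, seed, noise, compound="CPD"):
        spec = make_spec(noise=noise, seed=seed)
        responses = lb.process_study(lb.simulate_study(spec), "REF")
        datasets = lb.from_responses(responses)
        per_exp, combined = {}, {}
        for name in ("REF", compound):
            per_exp[name], combined[name] = {}, {}
            for pathway in (PATHWAY_ARR, PATHWAY_GQ):
                data = datasets[(name, pathway, "WT")]
                per_exp[name][pathway] = lb.fit_per_experiment(data)
                combined[name][pathway] = lb.fit_logistic3(data)
        return summarize_bias(
            compound, "REF", per_exp[compound], per_exp["REF"],
            combined[compound], combined["REF"],
        )

    def test_reference_beta_exactly_zero(self, noiseless_noise):
        result = self._study_bias(0, noiseless_noise, compound="REF")
        assert result.ok
        assert result.beta_per_experiment == [0.0, 0.0, 0.0]
        assert result.beta_mean == 0.0
        assert result.beta_combined == 0.0

    def test_no_heterogeneity_mean_equals_combined(self, noiseless_noise):
        """With no noise and no inter-experiment variability the averaged
        and the combined β coincide."""
        result = self._study_bias(0, noiseless_noise)
        assert result.ok
        assert result.beta_mean == pytest.approx(result.beta_combined, abs=1e-9)

    def test_too_few_experiments_is_nd(self):
        nd = LogisticFit.nd("flat")
        okf = fit(10, 100)
        per_exp = {PATHWAY_ARR: {"E1": okf, "E2": nd, "E3": nd},
                   PATHWAY_GQ: {"E1": okf, "E2": okf, "E3": okf}}
        ref = {PATHWAY_ARR: {"E1": okf, "E2": okf, "E3": okf},
               PATHWAY_GQ: {"E1": okf, "E2": okf, "E3": okf}}
        result = summarize_bias("C", "R", per_exp, ref,
                                {PATHWAY_ARR: okf, PATHWAY_GQ: okf},
                                {PATHWAY_ARR: okf, PATHWAY_GQ: okf})
        assert result.status == "nd"
        assert "experiments" in result.nd_reason

    def test_unbiased_compound_null(self):
        """A compound with identical pathway profile ratios to the reference
        has mean β within 2 SEM of zero over seeded noisy studies."""
        unbiased = (
            lb.CompoundSpec("REF", {"barr2": 12.9e-9, "miniGq": 13.2e-9},
                            {"barr2": 100.0, "miniGq": 100.0}),
            lb.CompoundSpec("CPD", {"barr2": 25.8e-9, "miniGq": 26.4e-9},
                            {"barr2": 60.0, "miniGq": 60.0}),
        )
        means = []
        for seed in range(60):
            spec = make_spec(compounds=unbiased, noise=NoiseModel(), seed=70_000 + seed)
            responses = lb.process_study(lb.simulate_study(spec), "REF")
            datasets = lb.from_responses(responses)
            per_exp, combined = {}, {}
            for name in ("REF", "CPD"):
                per_exp[name], combined[name] = {}, {}
                for pathway in (PATHWAY_ARR, PATHWAY_GQ):
                    data = datasets[(name, pathway, "WT")]
                    per_exp[name][pathway] = lb.fit_per_experiment(data)
                    combined[name][pathway] = lb.fit_logistic3(data)
            r = summarize_bias("CPD", "REF", per_exp["CPD"], per_exp["REF"],
                               combined["CPD"], combined["REF"])
            if r.ok:
                means.append(r.beta_mean)
        means = np.asarray(means)
        assert means.size >= 50
        sem = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 2 * sem


class TestSignificance:
    def test_kruskal_identical_groups_p_one(self):
        assert kruskal_wallis([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]]) == 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([[1.0, 2.0]])

    def test_dunn_separated_groups_significant(self):
        """{0,0,0} vs {5,5,5}: the Dunn z-comparison flags the difference at
        p < 0.05; the exact permutation enumeration of the rank sums gives
        its own (coarser, 2/20) p-value for reference."""
        p = dunn_vs_control({"R": [0.0, 0.0, 0.0], "C": [5.0, 5.0, 5.0]}, "R")
        assert p["C"] < 0.05
        exact = oracles.exact_rank_permutation_p([5.0, 5.0, 5.0], [0.0, 0.0, 0.0])
        assert exact == pytest.approx(2 / 20)

    def test_dunn_ordering_concordant_with_exact_permutation(self):
        """Across configurations of increasing separation, the Dunn p-values
        decrease monotonically with the exact-permutation p-values."""
        control = [0.0, 0.1, -0.1]
        configs = [[0.05, -0.02, 0.11], [0.3, 0.25, 0.4], [2.0, 2.2, 1.9]]
        dunn_ps, exact_ps = [], []
        for grp in configs:
            dunn_ps.append(
                dunn_vs_control({"R": control, "C": grp}, "R", adjust="none")["C"]
            )
            exact_ps.append(oracles.exact_rank_permutation_p(grp, control))
        assert sorted(dunn_ps, reverse=True) == dunn_ps
        assert sorted(exact_ps, reverse=True) == exact_ps

    def test_all_tied_dunn_p_one(self):
        p = dunn_vs_control({"R": [1.0, 1.0], "C": [1.0, 1.0]}, "R")
        assert p["C"] == 1.0

    def test_bias_significance_fills_pvalues_and_stars(self):
        results = [
            BiasResult("REF", "REF", [0.0, 0.0, 0.0], 0.0, 0.0),
            BiasResult("BIG", "REF", [1.2, 1.3, 1.25], 1.25, 1.25),
            BiasResult("NULL", "REF", [0.01, -0.02, 0.03], 0.007, 0.007),
            BiasResult("BAD", "REF", status="nd", nd_reason="x"),
        ]
        filled, kw_p = fill_significance(results)
        assert 0 <= kw_p <= 1
        big = next(r for r in filled if r.compound == "BIG")
        assert big.p_vs_reference is not None
        assert big.significance in ("*", "**", "")
        bad = next(r for r in filled if r.compound == "BAD")
        assert bad.p_vs_reference is None

    def test_type_one_error_at_most_nominal(self):
        """Unbiased compounds at n = 3 per group: the Holm-adjusted Dunn
        comparison rejects at well below the nominal 5% rate."""
        rejections, total = 0, 0
        for seed in range(300):
            rng = np.random.default_rng(20_000 + seed)
            results = [BiasResult("REF", "REF", [0.0, 0.0, 0.0], 0.0, 0.0)]
            for k in range(4):
                b = list(0.3 * rng.standard_normal(3))
                results.append(BiasResult(f"C{k}", "REF", b, float(np.mean(b)), None))
            filled, _ = fill_significance(results)
            for r in filled[1:]:
                total += 1
                rejections += r.p_vs_reference < 0.05
        mc_err = 2 * np.sqrt(0.05 * 0.95 / total)
        assert rejections / total <= 0.05 + mc_err


class TestCompareVariants:
    def test_identical_fits(self):
        f = fit(10, 100)
        cmp = compare_variants(f, f)
        assert cmp.fold_change_potency == pytest.approx(1.0)
        assert cmp.efficacy_drop == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "compound, pathway, expected_fold, expected_drop",
        [
            ("6a", PATHWAY_GQ, 137.0 / 8.59, 123.0 - 70.3),
            ("5-HT", PATHWAY_ARR, 661.0 / 12.1, 110.0 - 77.4),
            ("4a", PATHWAY_ARR, 172.0 / 11.1, 112.0 - 89.8),
        ],
    )
    def test_published_wt_vs_s159a(self, compound, pathway, expected_fold, expected_drop):
        wt = fit(*WT_FUNCTIONAL_DATA[compound][pathway])
        mut = fit(*S159A_FUNCTIONAL_DATA[compound][pathway])
        cmp = compare_variants(wt, mut, compound, pathway)
        assert cmp.fold_change_potency == pytest.approx(expected_fold, rel=1e-12)
        assert cmp.efficacy_drop == pytest.approx(expected_drop, rel=1e-12)

    def test_nd_propagates(self):
        assert compare_variants(fit(1, 100), LogisticFit.nd("x")).status == "nd"
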