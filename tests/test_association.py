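import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyassoc import (
    AssociationResult,
    ComparisonDesign,
    ContingencyTable,
    GenotypeCounts,
    STANDARD_DESIGNS,
    SeparationError,
    SimLocus,
    SyntheticConfig,
    ValidationError,
    allelic_counts,
    allelic_table,
    encode_model,
    fit_logistic,
    fit_logistic_or,
    generate_cohort,
    hwe_chi_square,
    odds_ratio,
    pearson_chi2,
    run_comparisons,
    subgroup_analysis,
)
from polyassoc.simulate import default_config


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_chi2(a, b, c, d):
    """Pearson chi-square from first principles: expected = row*col/N."""
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    n = a + b + c + d
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def grid_search_logistic(X, y, n_rounds=8, width=4.0, grid=11):
    """Coarse-to-fine likelihood maximization, independent of IRLS."""
    k = X.shape[1]
    center = np.zeros(k)
    for _ in range(n_rounds):
        axes = [np.linspace(c - width, c + width, grid) for c in center]
        best, best_ll = None, -np.inf
        mesh = np.meshgrid(*axes, indexing="ij")
        betas = np.stack([m.ravel() for m in mesh], axis=1)
        eta = X @ betas.T
        ll = (y[:, None] * eta - np.log1p(np.exp(eta))).sum(axis=0)
        best = betas[np.argmax(ll)]
        center = best
        width = width * 2.0 / (grid - 1)  # next grid spans two old cells
    return center


# ---------------------------------------------------------------------------
# Hardy-Weinberg

class TestHwe:
    def test_exact_proportions(self):
        res = hwe_chi_square(GenotypeCounts(25, 50, 25))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_4(self):
        res = hwe_chi_square(GenotypeCounts(30, 40, 30))
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=5e-5)

    def test_hand_computed_34(self):
        res = hwe_chi_square(GenotypeCounts(50, 20, 30))
        assert res.statistic == pytest.approx(34.0278, abs=1e-4)

    def test_monomorphic_degenerate(self):
        res = hwe_chi_square(GenotypeCounts(10, 0, 0))
        assert res.degenerate
        assert res.statistic == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            hwe_chi_square(GenotypeCounts(0, 0, 0))

    @given(
        n0=st.integers(0, 200), n1=st.integers(0, 200), n2=st.integers(0, 200)
    )
    def test_relabeling_invariance(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        a = hwe_chi_square(GenotypeCounts(n0, n1, n2))
        b = hwe_chi_square(GenotypeCounts(n2, n1, n0))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)


# ---------------------------------------------------------------------------
# odds ratios

class TestOddsRatio:
    def test_printed_counts(self):
        res = odds_ratio(ContingencyTable(69, 12, 57, 29))
        assert round(res.or_point, 2) == 2.93
        assert round(res.p_value, 4) == 0.0046

    def test_symmetric_table(self):
        res = odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert res.or_point == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_woolf_ci_hand_computed(self):
        # ln OR = 1.0733, SE = 0.3871
        res = odds_ratio(ContingencyTable(69, 12, 57, 29))
        assert res.ci_low == pytest.approx(1.37, abs=0.005)
        assert res.ci_high == pytest.approx(6.25, abs=0.005)

    def test_zero_cell_needs_haldane(self):
        with pytest.raises(ValidationError, match="haldane"):
            odds_ratio(ContingencyTable(5, 0, 3, 2))
        res = odds_ratio(ContingencyTable(5, 0, 3, 2), correction="haldane")
        assert res.or_point == pytest.approx((5.5 * 2.5) / (0.5 * 3.5))
        assert res.note == "haldane"

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 2, 3, 4)

    @given(
        a=st.integers(1, 200),
        b=st.integers(1, 200),
        c=st.integers(1, 200),
        d=st.integers(1, 200),
    )
    def test_swap_inverts_or_exactly(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert odds_ratio(t).or_point * odds_ratio(t.swapped()).or_point == (
            pytest.approx(1.0, rel=1e-12)
        )

    @given(
        a=st.integers(1, 80),
        b=st.integers(1, 80),
        c=st.integers(1, 80),
        d=st.integers(1, 80),
    )
    @settings(max_examples=200)
    def test_chi2_matches_brute_force(self, a, b, c, d):
        stat, _ = pearson_chi2(ContingencyTable(a, b, c, d))
        assert stat == pytest.approx(brute_force_chi2(a, b, c, d), rel=1e-10)

    def test_ci_brackets_point(self):
        res = odds_ratio(ContingencyTable(3, 7, 11, 2))
        assert res.ci_low <= res.or_point <= res.ci_high


# ---------------------------------------------------------------------------
# model encodings

class TestEncodeModel:
    def test_allelic_counts_arithmetic(self):
        assert allelic_counts(GenotypeCounts(10, 20, 30)) == (80, 40)

    def test_dominant(self):
        assert encode_model([0, 1, 2], "dominant").ravel().tolist() == [0, 1, 1]

    def test_recessive(self):
        assert encode_model([0, 1, 2], "recessive").ravel().tolist() == [0, 0, 1]

    def test_codominant_two_columns(self):
        X = encode_model([0, 1, 2], "codominant")
        assert X.tolist() == [[0, 0], [1, 0], [0, 1]]

    def test_missing_rejected(self):
        with pytest.raises(ValidationError):
            encode_model([0, -1, 2], "dominant")

    def test_unknown_model(self):
        with pytest.raises(ValidationError):
            encode_model([0, 1], "additive-ish")


# ---------------------------------------------------------------------------
# logistic regression

def _expand_table(a, b, c, d):
    """Per-subject arrays for a 2x2 table (exposure x case)."""
    x = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    y = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    return np.column_stack([np.ones_like(x), x]), y


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product(self):
        X, y = _expand_table(69, 12, 57, 29)
        beta, _ = fit_logistic(X, y)
        assert math.exp(beta[1]) == pytest.approx(
            odds_ratio(ContingencyTable(69, 12, 57, 29)).or_point, rel=1e-8
        )

    def test_random_tables_match_cross_product(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            X, y = _expand_table(int(a), int(b), int(c), int(d))
            beta, _ = fit_logistic(X, y)
            assert math.exp(beta[1]) == pytest.approx(
                a * d / (b * c), rel=1e-6
            )

    def test_separation_detected(self):
        # all cases exposed, all controls unexposed
        X, y = _expand_table(20, 0, 0, 20)
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_adjusted_or_matches_grid_search_oracle(self):
        # 400-subject cohort with a confounding sex effect
        cfg = SyntheticConfig(
            loci=(SimLocus("rs2294008", 0.3, 2.0),),
            n_cases_hered=0,
            n_cases_sporadic=200,
            n_controls=200,
            baseline_logit=-1.0,
            sex_effect=1.2,
            male_frac_sporadic=0.6,
            male_frac_controls=0.4,
            seed=11,
        )
        ds = generate_cohort(cfg)
        res = fit_logistic_or(
            ds, "rs2294008", "allelic", "cases-vs-controls", ("sex",)
        )
        from polyassoc.genotype_data import dose_matrix

        doses = dose_matrix(ds)[:, ds.snp_index("rs2294008")]
        y = np.array([s.is_case for s in ds.subjects], dtype=float)
        male = np.array([s.sex == "M" for s in ds.subjects], dtype=float)
        X = np.column_stack([np.ones_like(y), doses.astype(float), male])
        oracle = grid_search_logistic(X, y, n_rounds=14)
        assert math.log(res.or_point) == pytest.approx(oracle[1], abs=1e-4)


class TestFitLogisticOr:
    def test_wald_ci_brackets_or(self, table4_cohort):
        res = fit_logistic_or(
            table4_cohort, "rs4072037", "allelic", "cases-vs-controls"
        )
        assert res.ci_low < res.or_point < res.ci_high

    def test_codominant_returns_two_terms(self):
        ds = generate_cohort(default_config(seed=9))
        res = fit_logistic_or(
            ds, "rs2294008", "codominant", "cases-vs-controls"
        )
        assert isinstance(res, list) and len(res) == 2
        assert [r.term for r in res] == ["het", "hom"]

    def test_empty_group_rejected(self, table4_cohort):
        with pytest.raises(ValidationError):
            fit_logistic_or(
                table4_cohort, "rs4072037", "allelic", "casesA-vs-controls"
            )


class TestRunComparisons:
    def test_effective_n_matches_margins(self):
        ds = generate_cohort(default_config(seed=3))
        out = run_comparisons(ds, "rs4072037")
        assert out["cases-vs-controls"].effective_n == 116 + 102
        assert out["casesA-vs-controls"].effective_n == 65 + 102
        assert out["casesA-vs-casesB"].effective_n == 65 + 51
        assert out["cases-vs-controls"].adjusted_for == ("sex", "age")

    def test_no_controls_rejected(self):
        ds = generate_cohort(default_config(seed=3, n_controls=0))
        with pytest.raises(ValidationError, match="controls"):
            run_comparisons(ds, "rs4072037")

    def test_no_hereditary_cases_flagged_unavailable(self):
        ds = generate_cohort(default_config(seed=3, n_cases_hered=0))
        out = run_comparisons(ds, "rs4072037")
        assert out["cases-vs-controls"] is not None
        assert out["casesA-vs-controls"] is None
        assert out["casesA-vs-casesB"] is None

    def test_null_comparison_centered_on_one(self):
        # cases^A and cases^B share allele frequencies -> ln OR ~ 0 over seeds
        ln_ors = []
        for seed in range(200):
            cfg = SyntheticConfig(
                loci=(SimLocus("rs2294008", 0.4, 2.0, or_hereditary=2.0),),
                n_cases_hered=60,
                n_cases_sporadic=60,
                n_controls=40,
                baseline_logit=-1.0,
                seed=seed,
            )
            ds = generate_cohort(cfg)
            res = fit_logistic_or(
                ds, "rs2294008", "allelic", "casesA-vs-casesB"
            )
            ln_ors.append(math.log(res.or_point))
        mean = float(np.mean(ln_ors))
        se = float(np.std(ln_ors, ddof=1) / math.sqrt(len(ln_ors)))
        assert abs(mean) < 4 * se + 0.02


class TestSubgroups:
    def test_partition_property(self):
        ds = generate_cohort(default_config(seed=5))
        full = fit_logistic_or(
            ds, "rs2294008", "allelic", "casesA-vs-controls", ("age",)
        )
        strata = subgroup_analysis(ds, "rs2294008", "sex")
        assert sum(r.effective_n for _, r in strata) == full.effective_n

    def test_case_only_factor_uses_all_controls(self):
        ds = generate_cohort(default_config(seed=5))
        strata = dict(subgroup_analysis(ds, "rs2294008", "location"))
        n_controls = int(ds.status_mask("controls").sum())
        for res in strata.values():
            if not res.degenerate:
                assert res.effective_n <= 65 + n_controls
        assert strata["noncardia"].adjusted_for == ("sex", "age")

    def test_degenerate_level_flagged(self):
        # all hereditary cases share one genotype at the SNP -> no estimate
        cfg = SyntheticConfig(
            loci=(SimLocus("rs2294008", 0.0, 1.0, or_hereditary=1.0),),
            n_cases_hered=20,
            n_cases_sporadic=10,
            n_controls=20,
            baseline_logit=0.0,
            seed=2,
        )
        ds = generate_cohort(cfg)
        strata = subgroup_analysis(ds, "rs2294008", "sex")
        assert all(r.degenerate for _, r in strata)

    def test_unknown_factor(self):
        ds = generate_cohort(default_config(seed=5))
        with pytest.raises(ValidationError):
            subgroup_analysis(ds, "rs2294008", "blood-type")

    def test_sex_specific_effect_calibration(self):
        # true OR 3 in males, 1 in females: the male CI should exclude 1 and
        # the female CI cover 1 in >= 80% of seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                loci=(SimLocus("rs2294008", 0.3, 1.0),),
                n_cases_hered=0,
                n_cases_sporadic=500,
                n_controls=500,
                baseline_logit=-2.0,
                seed=seed,
            )
            ds = generate_cohort(cfg)
            # inject the male-only effect by resampling male case genotypes
            rng = np.random.default_rng(seed + 10_000)
            geno = ds.genotypes.copy()
            j = ds.snp_index("rs2294008")
            p, orr = 0.3, 3.0
            for i, s in enumerate(ds.subjects):
                if s.is_case and s.sex == "M":
                    # case genotype frequencies proportional to HWE * OR^dose
                    w = np.array(
                        [
                            (1 - p) ** 2,
                            2 * p * (1 - p) * orr,
                            p**2 * orr**2,
                        ]
                    )
                    dose = rng.choice(3, p=w / w.sum())
                    geno[i, j] = ["CC", "CT", "TT"][dose]
            from polyassoc import CohortDataset

            ds2 = CohortDataset(ds.snps, ds.subjects, geno, ds.age_window)
            strata = dict(subgroup_analysis(ds2, "rs2294008", "sex",
                                            design="cases-vs-controls"))
            male, female = strata["M"], strata["F"]
            if male.ci_low > 1.0 and female.ci_low <= 1.0 <= female.ci_high:
                hits += 1
        assert hits >= 0.8 * n_seeds
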