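import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pangls as pg
from pangls.io import DataValidationError


def make_qpcr(drought, water, isolate="iso1"):
    rows = []
    for cond, vals in (("drought", drought), ("water", water)):
        for r, v in enumerate(vals, start=1):
            rows.append({"isolate": isolate, "condition": cond,
                         "replicate": r, "abundance": float(v)})
    return pd.DataFrame(rows)


class TestStandardCurve:
    def test_linear_inversion_oracle(self):
        curve = pg.fit_standard_curve([(0, 30), (2, 24)])
        assert curve.slope == pytest.approx(-3.0)
        assert curve.intercept == pytest.approx(30.0)
        assert pg.interpolate_abundance(curve, 27.0) == pytest.approx(10.0)

    def test_collinear_points_r2_one(self):
        curve = pg.fit_standard_curve([(0, 30), (1, 27), (2, 24)])
        assert curve.r_squared == pytest.approx(1.0)

    def test_single_distinct_quantity_rejected(self):
        with pytest.raises(DataValidationError):
            pg.fit_standard_curve([(1, 30), (1, 24)])


class TestDEScores:
    def test_log2_ratio_of_means(self):
        de = pg.compute_de_scores(make_qpcr([4, 4, 4, 4], [2, 2, 2, 2]))
        assert de.loc["iso1", "de"] == pytest.approx(1.0)

    def test_equal_means_zero(self):
        de = pg.compute_de_scores(make_qpcr([3, 5], [4, 4]))
        assert de.loc["iso1", "de"] == pytest.approx(0.0)

    def test_depletion_negative(self):
        de = pg.compute_de_scores(make_qpcr([1, 1, 1, 1], [8, 8, 8, 8]))
        assert de.loc["iso1", "de"] == pytest.approx(-3.0)

    def test_antisymmetry_under_condition_swap(self, rng):
        tables = []
        rows = []
        for i in range(6):
            t = make_qpcr(rng.lognormal(size=4), rng.lognormal(size=4),
                          isolate=f"iso{i}")
            rows.append(t)
        table = pd.concat(rows, ignore_index=True)
        swapped = table.copy()
        swapped["condition"] = swapped["condition"].map(
            {"drought": "water", "water": "drought"})
        de1 = pg.compute_de_scores(table)["de"]
        de2 = pg.compute_de_scores(swapped)["de"]
        np.testing.assert_allclose(de1.values, -de2.values, atol=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(DataValidationError, match="replicates"):
            pg.compute_de_scores(make_qpcr([4], [2, 2]))

    def test_welch_matches_textbook_formula(self):
        d = np.array([3.0, 4.0, 5.0, 4.0])
        w = np.array([1.0, 2.0, 2.0, 1.0])
        de = pg.compute_de_scores(make_qpcr(d, w))
        # Welch by hand: t = (mean_d - mean_w)/sqrt(s_d^2/n + s_w^2/n),
        # Welch-Satterthwaite df, two-sided p from the t distribution.
        sd2, sw2 = d.var(ddof=1), w.var(ddof=1)
        se = np.sqrt(sd2 / 4 + sw2 / 4)
        t = (d.mean() - w.mean()) / se
        df = (sd2 / 4 + sw2 / 4) ** 2 / (
            (sd2 / 4) ** 2 / 3 + (sw2 / 4) ** 2 / 3)
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), df)
        assert de.loc["iso1", "t"] == pytest.approx(t, abs=1e-10)
        assert de.loc["iso1", "p"] == pytest.approx(p, abs=1e-10)

    def test_identical_groups_t_zero_p_one(self):
        de = pg.compute_de_scores(make_qpcr([1, 2, 3], [3, 1, 2]))
        assert de.loc["iso1", "t"] == pytest.approx(0.0)
        assert de.loc["iso1", "p"] == pytest.approx(1.0)


class TestBHAdjust:
    def test_stepup_example(self):
        q = pg.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2,
                    max_size=20))
    def test_order_invariance_and_monotonicity(self, ps):
        p = np.array(ps)
        q = pg.bh_adjust(p)
        # invariant to input ordering
        perm = np.argsort(p)[::-1]
        q_perm = pg.bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], rtol=1e-12)
        # monotone non-decreasing in sorted-p order, q >= p, q <= 1
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestPhenotypes:
    def test_water_content_formula(self):
        assert pg.water_content_percent(10.0, 2.0) == pytest.approx(80.0)

    def _pheno(self, treated_dry, mock_dry, cond="drought"):
        rows = []
        for iso, vals in (("isoA", treated_dry), ("mock", mock_dry)):
            for r, v in enumerate(vals, start=1):
                rows.append({"isolate": iso, "condition": cond, "replicate": r,
                             "fresh_mass": v * 4.0, "dry_mass": v})
        # the other condition needs a mock group too
        other = "water" if cond == "drought" else "drought"
        for r in (1, 2):
            rows.append({"isolate": "mock", "condition": other, "replicate": r,
                         "fresh_mass": 2.0, "dry_mass": 0.5})
        return pd.DataFrame(rows)

    def test_treated_equal_mock_delta_zero_p_one(self):
        eff = pg.compute_phenotype_deltas(self._pheno([0.4, 0.5, 0.6],
                                                      [0.6, 0.4, 0.5]))
        bio = eff[(eff["trait"] == "dry_mass") & (eff["condition"] == "drought")]
        assert bio["delta"].iloc[0] == pytest.approx(0.0)
        assert bio["p"].iloc[0] == pytest.approx(1.0)

    def test_known_shift_recovered_noiselessly(self):
        effects = pd.DataFrame({"water": [0.5], "drought": [0.5]},
                               index=["isoA"])
        wc = pd.Series([3.0], index=["isoA"])
        pheno = pg.simulate_phenotypes(["isoA"], biomass_effects=effects,
                                       wc_effects=wc, noise_sd=1e-9, seed=0)
        eff = pg.compute_phenotype_deltas(pheno)
        bio = eff[(eff["trait"] == "dry_mass") & (eff["condition"] == "water")]
        assert bio["delta"].iloc[0] == pytest.approx(0.5, abs=1e-6)
        wcrow = eff[eff["trait"] == "water_content"]
        assert wcrow["delta"].iloc[0] == pytest.approx(3.0, abs=1e-4)

    def test_missing_mock_is_error(self):
        pheno = self._pheno([0.4, 0.5], [0.6, 0.4])
        pheno = pheno[pheno["isolate"] != "mock"]
        with pytest.raises(DataValidationError, match="mock"):
            pg.compute_phenotype_deltas(pheno)


class TestCorrelation:
    def test_monotone_pairs(self):
        x = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        rho, _ = pg.correlate_de_phenotype(x, x * 3 + 1)
        assert rho == pytest.approx(1.0)
        rho, _ = pg.correlate_de_phenotype(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        x = pd.Series([1, 2, 3, 4.0], index=list("abcd"))
        with pytest.raises(DataValidationError, match="constant"):
            pg.correlate_de_phenotype(x, pd.Series(1.0, index=list("abcd")))

    def test_too_few_pairs_rejected(self):
        x = pd.Series([1, 2, 3.0], index=list("abc"))
        with pytest.raises(DataValidationError, match="4"):
            pg.correlate_de_phenotype(x, x)

    def test_type_i_error_near_alpha(self, rng):
        # independent vectors, n = 48: rejection rate at alpha = 0.05
        hits = 0
        reps = 400
        for _ in range(reps):
            x = pd.Series(rng.normal(size=48))
            y = pd.Series(rng.normal(size=48))
            _, p = pg.correlate_de_phenotype(x, y)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) < 0.03


class TestSimulatedRecovery:
    def test_noiseless_qpcr_inverts_exactly(self):
        true_de = pd.Series([1.0, -2.5, 0.0], index=["a", "b", "c"])
        table = pg.simulate_qpcr_experiment(true_de, tau=0.0, seed=1)
        de = pg.compute_de_scores(table)["de"]
        np.testing.assert_allclose(de.loc[["a", "b", "c"]].values,
                                   true_de.values, atol=1e-12)

    def test_noisy_qpcr_unbiased(self):
        n = 200
        true_de = pd.Series(np.zeros(n), index=[f"i{k}" for k in range(n)])
        table = pg.simulate_qpcr_experiment(true_de, tau=0.1, n_reps=4, seed=2)
        de = pg.compute_de_scores(table)["de"]
        se = de.std() / np.sqrt(n)
        assert abs(de.mean()) < 3 * se + 1e-3
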