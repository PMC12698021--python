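import numpy as np
import pandas as pd
import pytest

import pangls as pg
from pangls.io import DataValidationError
from pangls.screen import ScreenConfig, fit_association_models


def counts_frame(rows: dict, genomes: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=genomes)


class TestFilters:
    def setup_method(self):
        self.genomes = [f"iso{i:03d}" for i in range(1, 49)]

    def test_constant_column_dropped(self):
        m = counts_frame({"OGconst": [2] * 48, "OGvar": [0, 5] * 24},
                         self.genomes)
        kept, report = pg.filter_orthogroups(m, ScreenConfig())
        assert "OGconst" not in kept.index
        assert report["n_dropped_variance"] == 1

    def test_prevalence_ceiling_rule(self):
        # present in 11 of 48: threshold is ceil(0.25 * 48) = 12 -> dropped
        x = [3] * 11 + [0] * 37
        ok = [3] * 12 + [0] * 36
        m = counts_frame({"OG11": x, "OG12": ok}, self.genomes)
        kept, report = pg.filter_orthogroups(m, ScreenConfig())
        assert "OG11" not in kept.index
        assert "OG12" in kept.index
        assert report["prevalence_threshold"] == 12

    def test_high_variance_low_prevalence_dropped_by_prevalence_only(self):
        x = [0] * 47 + [5]
        assert np.var(x) == pytest.approx(0.5099, abs=1e-3)  # > 0.25
        m = counts_frame({"OGrare": x, "OGok": [0, 3] * 24}, self.genomes)
        kept, report = pg.filter_orthogroups(m, ScreenConfig())
        assert "OGrare" not in kept.index
        assert report["n_dropped_variance"] == 0
        assert report["n_dropped_prevalence"] == 1

    def test_filters_commute(self, rng):
        m = pd.DataFrame(rng.poisson(1.0, size=(80, 48)),
                         index=[f"OG{i}" for i in range(80)],
                         columns=self.genomes)
        cfg = ScreenConfig()
        kept, _ = pg.filter_orthogroups(m, cfg)
        # variance-then-prevalence equals prevalence-then-variance
        var_first = m[m.var(axis=1, ddof=0) > cfg.variance_min]
        both = var_first[(var_first >= 1).sum(axis=1) >= 12]
        assert list(kept.index) == list(both.index)

    def test_empty_result_is_error(self):
        m = counts_frame({"OGconst": [1] * 48}, self.genomes)
        with pytest.raises(DataValidationError, match="no orthogroups"):
            pg.filter_orthogroups(m, ScreenConfig())


class TestModelFitting:
    def test_aic_penalty_when_profile_hits_zero(self, yule48, rng):
        _, V = yule48
        # iid trait: profiled lambda typically 0, then AIC(free) = AIC(0) + 2
        for seed in range(10):
            r = np.random.default_rng(seed)
            rec = fit_association_models(r.standard_normal(48),
                                         r.poisson(3, 48).astype(float), V)
            if rec["lambda_free_lambda"] == 0.0:
                assert rec["lambda_free_aic"] == pytest.approx(
                    rec["lambda_0_aic"] + 2.0)
                assert rec["selected_model"] == "lambda_0"
                break
        else:
            pytest.fail("profiled lambda never hit 0 in 10 null draws")

    def test_null_prefers_lambda_zero(self, yule48):
        _, V = yule48
        rng = np.random.default_rng(77)
        chosen = []
        for _ in range(200):
            y = rng.standard_normal(48)
            x = rng.poisson(3, 48).astype(float)
            rec = fit_association_models(y, x, V)
            chosen.append(rec["selected_model"])
        frac_l0 = np.mean([c == "lambda_0" for c in chosen])
        assert frac_l0 >= 0.9

    def test_planted_slope_covered_by_2se(self, yule48):
        phy, V = yule48
        cfg = pg.SimConfig(n_orthogroups=50, n_planted=25, beta_true=0.5,
                           outgroup_label=None)
        hits = total = 0
        for seed in (1, 2, 3, 4):
            m, trait, planted = pg.simulate_copy_number_matrix(phy, cfg,
                                                               seed=seed)
            y = trait.loc[phy.tip_labels].to_numpy()
            for og in planted:
                x = m.loc[og, phy.tip_labels].to_numpy(float)
                rec = fit_association_models(y, x, V)
                total += 1
                hits += abs(rec["slope"] - 0.5) < 2 * rec["se"]
        assert hits / total >= 0.9


class TestRobustnessFilters:
    def base_record(self, **over):
        rec = {"slope": 0.5, "se": 0.1, "shapiro_p": 0.5, "fit_failed": False}
        rec.update(over)
        return rec

    def test_se_threshold(self):
        rec = pg.apply_robustness_filters(self.base_record(se=0.30),
                                          ScreenConfig())
        assert not rec["pass_se"] and not rec["significant"]

    def test_negative_slope_fails_signed_filter(self):
        rec = pg.apply_robustness_filters(self.base_record(slope=-0.6),
                                          ScreenConfig())
        assert not rec["pass_slope"]
        rec_abs = pg.apply_robustness_filters(
            self.base_record(slope=-0.6),
            ScreenConfig(slope_sign="absolute"))
        assert rec_abs["pass_slope"]

    def test_normality_filter(self):
        rec = pg.apply_robustness_filters(self.base_record(shapiro_p=0.01),
                                          ScreenConfig())
        assert not rec["pass_normality"]

    def test_heavy_tailed_residuals_rejected(self, yule48):
        # Cauchy traits produce non-normal residuals the SW filter catches
        _, V = yule48
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 100
        for _ in range(reps):
            y = rng.standard_cauchy(48)
            x = rng.poisson(3, 48).astype(float)
            rec = fit_association_models(y, x, V)
            rec = pg.apply_robustness_filters(rec, ScreenConfig())
            rejections += not rec["pass_normality"]
        assert rejections / reps >= 0.8


class TestRunScreen:
    def test_scale_halves_slope_and_se_jointly(self, yule48, rng):
        _, V = yule48
        y = rng.standard_normal(48)
        x = rng.poisson(3, 48).astype(float) + 1
        r1 = fit_association_models(y, x, V)
        r2 = fit_association_models(y, 2 * x, V)
        assert r2["slope"] == pytest.approx(r1["slope"] / 2, rel=1e-9)
        assert r2["se"] == pytest.approx(r1["se"] / 2, rel=1e-9)

    def test_null_slopes_centered_at_zero(self, yule48):
        phy, _ = yule48
        cfg = pg.SimConfig(n_orthogroups=300, n_planted=0,
                           outgroup_label=None)
        m, trait, _ = pg.simulate_copy_number_matrix(phy, cfg, seed=21)
        table, summary = pg.run_screen(m, trait, phy)
        slopes = table["slope"].dropna()
        se_mc = slopes.std() / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 3 * se_mc + 1e-3

    def test_planted_recovered_and_permutation_destroys_them(self, yule48):
        phy, _ = yule48
        cfg = pg.SimConfig(n_orthogroups=200, n_planted=15, beta_true=0.5,
                           outgroup_label=None)
        m, trait, planted = pg.simulate_copy_number_matrix(phy, cfg, seed=8)
        table, _ = pg.run_screen(m, trait, phy)
        sig = set(table.index[table["significant"]])
        recall = len(sig & set(planted)) / len(planted)
        assert recall >= 0.8
        # permuting the trait across genomes destroys the planted signal
        rng = np.random.default_rng(0)
        permuted = pd.Series(rng.permutation(trait.values), index=trait.index)
        table_p, _ = pg.run_screen(m, permuted, phy)
        sig_p = set(table_p.index[table_p["significant"]])
        assert len(sig_p & set(planted)) <= 2

    def test_output_sorted_and_deterministic(self, yule48):
        phy, _ = yule48
        cfg = pg.SimConfig(n_orthogroups=40, n_planted=5, outgroup_label=None)
        m, trait, _ = pg.simulate_copy_number_matrix(phy, cfg, seed=2)
        t1, _ = pg.run_screen(m, trait, phy)
        shuffled = m.sample(frac=1.0, random_state=1)
        t2, _ = pg.run_screen(shuffled, trait, phy)
        assert list(t1.index) == sorted(t1.index)
        pd.testing.assert_frame_equal(t1, t2)
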