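"""GLM machinery, stepwise building, GWAS filters, FDR and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sweepscan.association import (
    cnv_power_simulation,
    contamination_filter,
    fdr_select,
    glm_binomial,
    marker_tests,
    snp_gwas,
    stepwise_build,
    windowed_gwas,
)

from conftest import make_genotypes, make_sample_table


class TestGlmBinomial:
    def test_two_by_two_closed_form(self):
        # non-carrier 20 dead / 10 alive, carrier 10 dead / 30 alive
        y = np.r_[np.zeros(20), np.ones(10), np.zeros(10), np.ones(30)]
        x = np.r_[np.zeros(30), np.ones(40)]
        res = glm_binomial(y, pd.DataFrame({"carrier": x}))
        assert res.coefficients[1] == pytest.approx(np.log(6), abs=1e-9)
        assert not res.separation

    def test_binary_predictor_equals_log_odds_ratio(self, rng):
        # exact identity wherever all four table cells are positive
        for _ in range(30):
            a, b, c, d = rng.integers(1, 40, 4)
            y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            x = np.r_[np.ones(a + b), np.zeros(c + d)]
            res = glm_binomial(y, pd.DataFrame({"m": x}))
            lor = np.log((a * d) / (b * c))
            assert res.coefficients[1] == pytest.approx(lor, abs=1e-7)
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert res.std_errors[1] == pytest.approx(se, rel=1e-5)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.binomial(2, 0.3, n).astype(float)
        eta = -0.5 + 0.8 * x1 - 0.4 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = glm_binomial(y, pd.DataFrame({"x1": x1, "x2": x2}))
        ref = sm.GLM(y, sm.add_constant(np.column_stack([x1, x2])),
                     family=sm.families.Binomial()).fit()
        assert np.allclose(res.coefficients, ref.params, atol=1e-6)
        assert np.allclose(res.std_errors, ref.bse, atol=1e-6)
        assert res.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_null_p_values_calibrated(self, rng):
        ps = []
        for _ in range(60):
            x = rng.binomial(2, 0.3, 300).astype(float)
            y = rng.binomial(1, 0.5, 300).astype(float)
            ps.append(glm_binomial(y, pd.DataFrame({"x": x})).p_wald[1])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_perfect_separation_flag_and_lrt(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()
        res = glm_binomial(y, pd.DataFrame({"m": x}))
        assert res.separation
        p = res.p_for("m")
        assert 0 < p < 1e-6  # LRT fallback is decisive, Wald would be ~1

    def test_constant_predictor_dropped(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        res = glm_binomial(
            y, pd.DataFrame({"c": np.ones(10), "x": np.r_[np.ones(5), np.zeros(5)]})
        )
        assert res.dropped == ["c"]
        assert "c" not in res.terms

    def test_single_class_phenotype_rejected(self):
        with pytest.raises(ValueError):
            glm_binomial(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestMarkerTests:
    def test_dose_coding_enters_numerically(self, rng):
        y = rng.binomial(1, 0.5, 100)
        dose = rng.integers(0, 3, 100).astype(float)
        st = make_sample_table(
            [f"S{i}" for i in range(100)],
            phenotypes=["resistant" if v else "susceptible" for v in y],
        )
        table = marker_tests(st, pd.DataFrame({"snp": dose}))
        ref = glm_binomial(y.astype(float), pd.DataFrame({"snp": dose}))
        assert table.loc[0, "coefficient"] == pytest.approx(ref.coefficients[1])

    def test_constant_marker_reported_nan(self):
        st = make_sample_table([f"S{i}" for i in range(10)])
        table = marker_tests(st, pd.DataFrame({"flat": np.ones(10)}))
        assert np.isnan(table.loc[0, "p"])


class TestStepwise:
    def make_st(self, y):
        return make_sample_table(
            [f"S{i}" for i in range(len(y))],
            phenotypes=["resistant" if v else "susceptible" for v in y],
        )

    def test_null_markers_give_null_model(self, rng):
        y = rng.binomial(1, 0.5, 80)
        markers = pd.DataFrame(
            {f"m{k}": rng.binomial(1, 0.5, 80).astype(float) for k in range(4)}
        )
        # permute y freshly so markers are independent of phenotype
        sw = stepwise_build(self.make_st(y), markers, alpha=0.001)
        assert sw.selected == []
        assert sw.final is None

    def test_collinear_markers_one_enters(self, rng):
        carrier = rng.binomial(1, 0.5, 120).astype(float)
        p_alive = np.where(carrier == 1, 0.8, 0.3)
        y = (rng.random(120) < p_alive).astype(int)
        markers = pd.DataFrame({"geneA": carrier, "geneB": carrier.copy()})
        sw = stepwise_build(self.make_st(y), markers)
        assert sw.selected == ["geneA"]  # second copy adds nothing

    def test_causal_first_and_loglik_monotone(self, rng):
        n = 150
        carrier = rng.binomial(1, 0.5, n).astype(float)
        p_alive = np.where(carrier == 1, 0.85, 0.35)
        y = (rng.random(n) < p_alive).astype(int)
        markers = {"causal": carrier}
        for k in range(9):
            markers[f"null{k}"] = rng.binomial(2, 0.3, n).astype(float)
        sw = stepwise_build(self.make_st(y), pd.DataFrame(markers))
        assert sw.selected[0] == "causal"
        lls = [s[2] for s in sw.steps]
        assert all(b >= a for a, b in zip(lls, lls[1:]))
        assert all(s[1] < 0.05 for s in sw.steps)


class TestContaminationFilter:
    def test_tracking_site_excluded(self, rng):
        n = 120
        contam = rng.uniform(0, 0.05, n)
        calls = rng.binomial(2, 0.3, size=(10, n)).astype(np.int8)
        calls[0] = (contam > np.median(contam)).astype(np.int8) * 2
        g = make_genotypes(calls)
        st = make_sample_table(g.samples, contamination=contam)
        retained = contamination_filter(g, st)
        assert 0 not in retained

    def test_zero_variance_contamination_keeps_all(self, rng):
        calls = rng.binomial(2, 0.3, size=(8, 30)).astype(np.int8)
        g = make_genotypes(calls)
        st = make_sample_table(g.samples, contamination=0.01)
        assert len(contamination_filter(g, st)) == 8


class TestFdr:
    def test_all_ones_empty(self):
        table = pd.DataFrame({"contig": "2L", "pos": range(1, 11), "p": 1.0})
        assert fdr_select(table, q=0.01).empty

    def test_bh_step_up_by_hand(self):
        # step-up: select ranks k with p(k) <= k/m * q. With m = 1000 and
        # q = 0.01 the rank-10 cutoff is 1e-4, so p = 1e-6 passes and
        # p = 0.001 does not (adjusted value 0.001*1000/10 = 0.1 > q).
        ps = [1e-6] * 10 + [0.9] * 990
        table = pd.DataFrame({"contig": "2L", "pos": range(1, 1001), "p": ps})
        out = fdr_select(table, q=0.01)
        assert len(out) == 10
        assert (out["p"] == 1e-6).all()
        assert out["q_value"].max() == pytest.approx(1e-4, rel=1e-9)
        marginal = pd.DataFrame(
            {"contig": "2L", "pos": range(1, 1001), "p": [0.001] * 10 + [0.9] * 990}
        )
        assert fdr_select(marginal, q=0.01).empty


class TestWindowedGwas:
    def make_table(self, positions, ps, contig="2L"):
        return pd.DataFrame({"contig": contig, "pos": positions, "p": ps})

    def test_twelve_hits_flagged_nine_not(self, rng):
        pos_hot = rng.choice(np.arange(200_001, 300_000), 12, replace=False)
        pos_warm = rng.choice(np.arange(500_001, 600_000), 9, replace=False)
        pos_rest = rng.choice(np.arange(1_000_001, 5_000_000), 979, replace=False)
        table = self.make_table(
            np.r_[pos_hot, pos_warm, pos_rest], np.full(1000, 1e-4)
        )
        out = windowed_gwas(table, top_n=1000, min_hits=10)
        assert 200_000 in out["win_start"].tolist()
        assert 500_000 not in out["win_start"].tolist()

    def test_matches_brute_force_recount(self, rng):
        for _ in range(10):
            n = 400
            pos = np.sort(rng.choice(np.arange(1, 2_000_000), n, replace=False))
            ps = rng.random(n)
            table = self.make_table(pos, ps)
            top_n, min_hits = 100, 4
            out = windowed_gwas(table, top_n=top_n, min_hits=min_hits)
            ranked = table.sort_values(["p", "pos"]).head(top_n)
            counts = {}
            for p in ranked["pos"]:
                counts[(p - 1) // 100_000] = counts.get((p - 1) // 100_000, 0) + 1
            expected = sorted(t * 100_000 for t, c in counts.items() if c >= min_hits)
            assert out["win_start"].tolist() == expected

    def test_empty_table(self):
        out = windowed_gwas(pd.DataFrame(columns=["contig", "pos", "p"]))
        assert out.empty


class TestSnpGwas:
    def test_missing_call_site_absent(self, rng):
        calls = rng.binomial(2, 0.4, size=(6, 40)).astype(np.int8)
        calls[2, 0] = -1
        g = make_genotypes(calls)
        st = make_sample_table(g.samples)
        table = snp_gwas(g, st, min_mac=1)
        assert g.sites[2].pos not in table["pos"].tolist()

    def test_planted_effect_ranks_high(self, rng):
        n, n_sites = 160, 300
        causal = rng.binomial(2, 0.3, n).astype(np.int8)
        logit = -0.5 + np.log(4) * causal
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, n_sites)[:, None],
                             (n_sites, n)).astype(np.int8)
        calls[n_sites // 2] = causal
        g = make_genotypes(calls)
        st = make_sample_table(
            g.samples,
            phenotypes=["resistant" if v else "susceptible" for v in y],
        )
        table = snp_gwas(g, st)
        causal_pos = g.sites[n_sites // 2].pos
        rank = table.sort_values("p").reset_index(drop=True)
        top = rank.head(10)["pos"].tolist()
        assert causal_pos in top


class TestPower:
    def test_type_one_error_under_null(self):
        res = cnv_power_simulation(200, 0.5, 0.4, 0.4, n_sims=400, seed=11)
        assert res.power == pytest.approx(0.05, abs=0.04)

    def test_perfect_separation_power_one(self):
        res = cnv_power_simulation(60, 0.5, 1.0, 0.0, n_sims=100, seed=3)
        assert res.power >= 0.99

    def test_deterministic_under_seed(self):
        a = cnv_power_simulation(100, 0.5, 0.5, 0.2, n_sims=50, seed=9)
        b = cnv_power_simulation(100, 0.5, 0.5, 0.2, n_sims=50, seed=9)
        assert a.power == b.power

    def test_se_formula(self):
        res = cnv_power_simulation(100, 0.5, 0.5, 0.2, n_sims=50, seed=9)
        assert res.mc_se == pytest.approx(
            np.sqrt(res.power * (1 - res.power) / 50)
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            cnv_power_simulation(100, 1.5, 0.5, 0.2)
        with pytest.raises(ValueError):
            cnv_power_simulation(1, 0.5, 0.5, 0.2)
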