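"""Permutation tests against enumeration oracles, FDR, correlations, mixed models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from cycdbs.stats import (
    cluster_perm_paired,
    fdr_bh,
    glmm_taprate,
    lme_li_frequency,
    paired_effect_size,
    pearson,
    rate_ratio_on_off,
    tap_rates,
    tmax_perm_onesample,
)
from cycdbs.synth import make_schedule, simulate_tapping

from conftest import fast_config


def chain_adjacency(n):
    adj = np.zeros((n, n), bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def brute_force_cluster(x, adj, alpha=0.05):
    """Independent enumeration oracle for the paired cluster test."""
    n, nch = x.shape
    thr = sstats.t.ppf(1 - alpha / 2, n - 1)

    def tmap(d):
        return d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))

    def clusters(t):
        out = []
        for sign in (1, -1):
            mask = sign * t > thr
            seen = set()
            for s in range(nch):
                if mask[s] and s not in seen:
                    comp = {s}
                    stack = [s]
                    while stack:
                        u = stack.pop()
                        for v in range(nch):
                            if adj[u, v] and mask[v] and v not in comp:
                                comp.add(v)
                                stack.append(v)
                    seen |= comp
                    out.append((tuple(sorted(comp)), t[list(comp)].sum()))
        return out

    obs = clusters(tmap(x))
    null = []
    for signs in itertools.product([1, -1], repeat=n):
        cl = clusters(tmap(x * np.array(signs)[:, None]))
        null.append(max([abs(m) for _, m in cl], default=0.0))
    null = np.asarray(null)
    return obs, [(null >= abs(m) - 1e-12).sum() / null.size for _, m in obs]


class TestClusterPerm:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.3, 1.0, (5, 8))
        adj = chain_adjacency(8)
        res = cluster_perm_paired(x, np.zeros_like(x), adj)
        assert res.exhaustive and res.n_permutations == 32
        obs, p_oracle = brute_force_cluster(x, adj)
        assert [tuple(c) for c in res.clusters] == [c for c, _ in obs]
        assert np.allclose(res.p_values, p_oracle)
        assert np.allclose([m for _, m in obs], res.cluster_stats)

    def test_identical_conditions_never_significant(self):
        adj = chain_adjacency(12)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=(10, 12))
            res = cluster_perm_paired(x, x.copy(), adj, n_permutations=200,
                                      rng=rng)
            assert not res.clusters  # zero differences -> no supra-threshold t

    def test_shifted_block_detected(self):
        rng = np.random.default_rng(1)
        adj = chain_adjacency(20)
        x = rng.normal(size=(10, 20))
        shifted = x.copy()
        shifted[:, 4:12] += 3.0  # +3 SD in an 8-channel connected block
        res = cluster_perm_paired(shifted, x * 0, adj, n_permutations=500,
                                  rng=rng)
        best = res.clusters[np.argmin(res.p_values)]
        assert res.p_values.min() <= 0.05
        assert len(set(best) & set(range(4, 12))) >= 6

    def test_channel_reordering_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 1.0, (6, 8))
        adj = chain_adjacency(8)
        perm = rng.permutation(8)
        adj_p = adj[np.ix_(perm, perm)]
        res_a = cluster_perm_paired(x, np.zeros_like(x), adj)
        res_b = cluster_perm_paired(x[:, perm], np.zeros((6, 8)), adj_p)
        assert sorted(np.round(res_a.p_values, 12)) == sorted(np.round(res_b.p_values, 12))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_perm_paired(np.zeros((2, 4)), np.zeros((2, 4)),
                                chain_adjacency(4))


class TestTmax:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.5, 1.0, (5, 6))
        res = tmax_perm_onesample(vals)
        assert res.exhaustive
        t_obs = vals.mean(0) / (vals.std(0, ddof=1) / np.sqrt(5))
        null = []
        for signs in itertools.product([1, -1], repeat=5):
            x = vals * np.array(signs)[:, None]
            null.append(np.abs(x.mean(0) / (x.std(0, ddof=1) / np.sqrt(5))).max())
        null = np.asarray(null)
        oracle = [(null >= abs(t) - 1e-12).sum() / 32 for t in t_obs]
        assert np.allclose(res.p_adjusted, oracle)

    def test_exhaustive_p_values_are_multiples_of_grid(self):
        rng = np.random.default_rng(8)
        res = tmax_perm_onesample(rng.normal(size=(6, 4)))
        grid = res.p_adjusted * 64
        assert np.allclose(grid, np.round(grid))

    def test_strong_single_bin_reaches_floor(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.001, (5, 4))
        vals[:, 2] += 1.0
        res = tmax_perm_onesample(vals)
        # two-sided max|t|: identity and the global sign flip tie -> 2/32
        assert res.p_adjusted[2] == pytest.approx(2 / 32)

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0.3, 1.0, (10, 5))
        exact = tmax_perm_onesample(vals)
        mc = tmax_perm_onesample(vals, n_permutations=10000,
                                 rng=np.random.default_rng(0),
                                 max_exhaustive=4)
        assert not mc.exhaustive
        assert np.max(np.abs(mc.p_adjusted - exact.p_adjusted)) < 0.02


class TestFdrAndPearson:
    def test_hand_computed_step_up(self):
        rej, padj = fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert rej.all()
        rej2, _ = fdr_bh([0.06], alpha=0.05)
        assert not rej2.any()
        rej3, padj3 = fdr_bh([1.0, 1.0, 1.0])
        assert not rej3.any() and np.allclose(padj3, 1.0)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=40)
        _, padj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(padj[order]) >= -1e-12)

    def test_pearson_exact_lines(self):
        x = np.arange(10.0)
        r, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = pearson(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_pearson_null_calibration(self):
        rng = np.random.default_rng(12)
        rej = 0
        n_sim = 1000
        rs = []
        for _ in range(n_sim):
            r, p = pearson(rng.normal(size=14), rng.normal(size=14))
            rs.append(r)
            rej += p < 0.05
        assert abs(np.mean(rs)) < 0.02
        assert rej / n_sim == pytest.approx(0.05, abs=0.02)


def _lme_data(rng, n_subj=10, effect=None, subj_sd=0.08, noise=0.05):
    effect = effect or {}
    rows = []
    for s in range(n_subj):
        b = rng.normal(0, subj_sd)
        for f in [10, 16, 20, 26, 30]:
            rows.append({"participant": s, "dbs_frequency": f,
                         "normalized_li": 0.1 + b + effect.get(f, 0.0)
                         + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestLme:
    def test_zero_random_variance_equals_oneway_anova(self):
        rng = np.random.default_rng(1)
        df = _lme_data(rng, subj_sd=0.0)
        res = lme_li_frequency(df)
        groups = [df[df.dbs_frequency == f]["normalized_li"]
                  for f in [10, 16, 20, 26, 30]]
        F, _ = sstats.f_oneway(*groups)
        assert res.statistic == pytest.approx(F, abs=1e-6)

    def test_matches_satterthwaite_reference_fit(self):
        """Frozen oracle from an independent REML/Satterthwaite implementation
        on the identical dataset: F(4, 36.0) = 18.6909, p = 2.154e-08."""
        rng = np.random.default_rng(2024)
        df = _lme_data(rng, effect={30: 0.15})
        res = lme_li_frequency(df)
        assert res.stat_name == "F"
        assert res.statistic == pytest.approx(18.6909, rel=2e-3)
        assert res.df[0] == 4 and res.df[1] == pytest.approx(36.0, abs=0.1)
        assert res.p_value == pytest.approx(2.154e-08, rel=0.05)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(13)
        rej = sum(lme_li_frequency(_lme_data(rng)).p_value < 0.05
                  for _ in range(100))
        assert 1 <= rej <= 12  # ~5% nominal

    def test_power_for_large_shift(self):
        rng = np.random.default_rng(14)
        rej = sum(
            lme_li_frequency(_lme_data(rng, effect={30: 0.4})).p_value < 0.05
            for _ in range(20)
        )
        assert rej >= 19  # +5 between-subject SDs: essentially always detected


def _glmm_data(rng, ratio=0.9, rate=120.0, n_subj=14, subj_sd=0.08):
    rows = []
    for s in range(n_subj):
        b = rng.normal(0, subj_sd)
        for f in [10, 16, 20, 26, 30]:
            for state, x in (("on", 0.5), ("off", -0.5)):
                exposure = 60.0 if state == "on" else 45.0
                mu = rate * np.exp(b + np.log(ratio) * x) * exposure / 60.0
                rows.append({"participant": s, "dbs_frequency": f,
                             "state": state, "tap_count": rng.poisson(mu),
                             "exposure_s": exposure})
    return pd.DataFrame(rows)


class TestGlmm:
    def test_matches_reference_mixed_model_fit(self):
        """Frozen oracle from an independent Laplace/ML Poisson mixed-model fit
        on the identical dataset (fixed effects and likelihood-ratio chi2)."""
        rng = np.random.default_rng(7)
        rows = []
        for s in range(14):
            b = rng.normal(0, 0.1)
            for f in [10, 16, 20, 26, 30]:
                for state, x in (("on", 0.5), ("off", -0.5)):
                    eta = np.log(2.0) + b + np.log(0.9) * x
                    exposure = rng.uniform(50, 70)
                    mu = np.exp(eta) * exposure / 60.0
                    rows.append({"participant": s, "dbs_frequency": f,
                                 "state": state, "tap_count": rng.poisson(mu),
                                 "exposure_s": exposure})
        res = glmm_taprate(pd.DataFrame(rows))
        expected = [0.654028, 0.005878, 0.039850, 0.182678, 0.026150,
                    -0.231502, 0.058024, -0.071814, -0.216010, 0.355463]
        assert np.allclose(res.params.to_numpy()[:10], expected, atol=1e-3)
        assert res.effects["frequency"][0] == pytest.approx(4.6416, abs=0.01)
        assert res.effects["interaction"][0] == pytest.approx(2.3324, abs=0.01)

    def test_rate_ratio_recovered(self):
        rng = np.random.default_rng(15)
        res = glmm_taprate(_glmm_data(rng, ratio=0.9))
        assert 0.85 <= rate_ratio_on_off(res) <= 0.95

    def test_offset_invariance(self):
        rng = np.random.default_rng(16)
        df = _glmm_data(rng)
        df2 = df.copy()
        df2["tap_count"] *= 2
        df2["exposure_s"] *= 2
        a = glmm_taprate(df)
        b = glmm_taprate(df2)
        assert rate_ratio_on_off(a) == pytest.approx(rate_ratio_on_off(b), abs=0.01)

    def test_zero_exposure_row_dropped(self):
        rng = np.random.default_rng(17)
        df = _glmm_data(rng)
        df.loc[0, "exposure_s"] = 0.0
        res = glmm_taprate(df)  # must not raise
        assert res.converged


class TestTapRates:
    def test_constant_rate_both_states(self):
        cfg = fast_config(li_tap_coupling=0.0, tap_rate_base=120.0, tap_shape=50.0)
        sched = make_schedule(cfg.tapping_duration, 20.0)
        ev, _ = simulate_tapping(sched, cfg, rng=np.random.default_rng(3))
        tr = tap_rates(ev, sched)
        on = tr[tr.state == "on"].iloc[0]
        off = tr[tr.state == "off"].iloc[0]
        assert on["rate"] == pytest.approx(120.0, rel=0.06)
        assert off["rate"] == pytest.approx(120.0, rel=0.06)
        assert on["rate"] == pytest.approx(on["tap_count"] / on["exposure_s"] * 60)

    def test_taps_only_during_off(self):
        cfg = fast_config()
        sched = make_schedule(cfg.tapping_duration, 20.0)
        ev, _ = simulate_tapping(sched, cfg, rng=np.random.default_rng(4))
        df = ev.df[~((ev.df.event_type == "tap") & (ev.df.condition == "on"))]
        from cycdbs.core import EventTable

        tr = tap_rates(EventTable(df), sched)
        assert tr[tr.state == "on"].iloc[0]["rate"] == 0.0
        assert tr[tr.state == "off"].iloc[0]["rate"] > 0

    def test_injected_on_off_rates_recovered(self):
        cfg = fast_config(tap_rate_base=120.0, li_tap_coupling=100.0)
        sched = make_schedule(cfg.tapping_duration, 20.0)
        on_rates, off_rates = [], []
        for seed in range(25):
            ev, _ = simulate_tapping(sched, cfg, subject_li=0.0, delta_li=0.1,
                                     rng=np.random.default_rng(seed))
            tr = tap_rates(ev, sched)
            on_rates.append(tr[tr.state == "on"].iloc[0]["rate"])
            off_rates.append(tr[tr.state == "off"].iloc[0]["rate"])
        assert np.mean(off_rates) == pytest.approx(120.0, rel=0.04)
        assert np.mean(on_rates) == pytest.approx(110.0, rel=0.04)
        eff = paired_effect_size(np.array(on_rates), np.array(off_rates))
        assert eff["mean_difference"] < 0
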