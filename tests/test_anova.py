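"""Repeated-measures ANOVA, normality gate, rank fallback, power analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cardiosym.anova import (
    PowerQuery,
    RepeatedMeasuresAnova,
    deltas,
    kruskal_fallback,
    rm_anova_power,
    rm_sample_size,
    shapiro_gate,
)


def brute_force_two_way(y):
    """From-scratch fully-within decomposition by explicit mean subtraction.

    ``y`` has shape (subjects, A levels, B levels); returns SS per term.
    """
    n, a, b = y.shape
    g = y.mean()
    ss = {}
    # explicit loops, no vectorised shortcuts
    ss["A"] = sum(n * b * (y[:, i, :].mean() - g) ** 2 for i in range(a))
    ss["B"] = sum(n * a * (y[:, :, j].mean() - g) ** 2 for j in range(b))
    ss["S"] = sum(a * b * (y[s].mean() - g) ** 2 for s in range(n))
    ss["AB"] = sum(
        n * (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + g) ** 2
        for i in range(a)
        for j in range(b)
    )
    ss["AS"] = sum(
        b * (y[s, i, :].mean() - y[:, i, :].mean() - y[s].mean() + g) ** 2
        for s in range(n)
        for i in range(a)
    )
    ss["BS"] = sum(
        a * (y[s, :, j].mean() - y[:, :, j].mean() - y[s].mean() + g) ** 2
        for s in range(n)
        for j in range(b)
    )
    ss["total"] = float(((y - g) ** 2).sum())
    ss["ABS"] = ss["total"] - sum(ss[k] for k in ("A", "B", "S", "AB", "AS", "BS"))
    return ss


def long_format(y, subject="subject"):
    n, a, b = y.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append({subject: f"S{s}", "A": f"a{i}", "B": f"b{j}",
                             "y": y[s, i, j]})
    return pd.DataFrame(rows)


class TestRMAnova:
    def test_toy_table_matches_brute_force(self):
        """SS and F of a small 3×3 crossover equal the explicit-mean oracle."""
        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, size=(4, 3, 3))
        ss = brute_force_two_way(y)
        res = RepeatedMeasuresAnova(long_format(y), "y", within=("A", "B")).fit()
        ea = res.effect("A")
        assert ea.ss == pytest.approx(ss["A"], rel=1e-10)
        assert ea.ss_error == pytest.approx(ss["AS"], rel=1e-10)
        f_expected = (ss["A"] / 2) / (ss["AS"] / 6)
        assert ea.f_value == pytest.approx(f_expected, rel=1e-10)
        eb = res.effect("B")
        assert eb.ss == pytest.approx(ss["B"], rel=1e-10)
        assert eb.ss_error == pytest.approx(ss["BS"], rel=1e-10)
        eab = res.effect("A:B")
        assert eab.ss == pytest.approx(ss["AB"], rel=1e-10)
        assert eab.ss_error == pytest.approx(ss["ABS"], rel=1e-8)
        # partial eta squared definition
        assert ea.partial_eta_sq == pytest.approx(
            ss["A"] / (ss["A"] + ss["AS"]), rel=1e-10)

    def test_total_ss_decomposition(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(6, 3, 4))
        ss = brute_force_two_way(y)
        parts = sum(ss[k] for k in ("A", "B", "S", "AB", "AS", "BS", "ABS"))
        assert parts == pytest.approx(ss["total"], rel=1e-10)

    def test_one_way_matches_pingouin(self):
        """Independent cross-check of F, p, GG ε and sphericity."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        n = 14
        y = rng.normal(0, 1, size=(n, 3, 1))
        y[:, 1, 0] += 0.8
        data = long_format(y)
        res = RepeatedMeasuresAnova(data, "y", within="A").fit()
        ref = pg.rm_anova(data=data, dv="y", within="A", subject="subject",
                          correction=True, detailed=True)
        ref = ref.set_index("Source")
        ea = res.effect("A")
        assert ea.f_value == pytest.approx(float(ref.loc["A", "F"]), rel=1e-8)
        assert ea.p_uncorrected == pytest.approx(
            float(ref.loc["A", "p_unc"]), rel=1e-8)
        assert ea.sphericity.gg_epsilon == pytest.approx(
            float(ref.loc["A", "eps"]), rel=1e-6)
        assert ea.p_gg == pytest.approx(float(ref.loc["A", "p_GG_corr"]), rel=1e-6)
        sph = pg.sphericity(data=data, dv="y", within="A", subject="subject")
        assert ea.sphericity.mauchly_w == pytest.approx(float(sph.W), rel=1e-8)
        assert ea.sphericity.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)

    def test_compound_symmetry_has_unit_epsilon(self):
        """A compound-symmetric covariance is exactly spherical: GG ε = 1.

        Built analytically: subject effect + iid noise gives CS in
        expectation; here we symmetrise the sample so ε̂ is exactly 1.
        """
        # construct data whose contrast covariance is proportional to I
        rng = np.random.default_rng(3)
        n, m = 40, 3
        # orthonormal contrast scores drawn iid, then mapped back
        from cardiosym.anova import _orthonormal_contrasts

        c = _orthonormal_contrasts(m)
        scores = rng.normal(size=(n, m - 1))
        # whiten the sample exactly
        cov = np.cov(scores, rowvar=False, ddof=1)
        scores = scores @ np.linalg.inv(np.linalg.cholesky(cov)).T
        y = (scores @ c)[:, :, None] + rng.normal(size=(n, 1, 1))
        res = RepeatedMeasuresAnova(long_format(y), "y", within="A").fit()
        assert res.effect("A").sphericity.gg_epsilon == pytest.approx(1.0, abs=1e-9)

    def test_unbalanced_design_rejected(self):
        y = np.random.default_rng(0).normal(size=(4, 3, 1))
        data = long_format(y).iloc[:-1]  # drop one cell
        with pytest.raises(ValueError, match="unbalanced"):
            RepeatedMeasuresAnova(data, "y", within="A").fit()

    def test_eta_invariant_under_affine_response_rescaling(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(8, 3, 2))
        data = long_format(y)
        res1 = RepeatedMeasuresAnova(data, "y", within=("A", "B")).fit()
        data2 = data.assign(y=3.7 * data["y"] - 11.0)
        res2 = RepeatedMeasuresAnova(data2, "y", within=("A", "B")).fit()
        for e1, e2 in zip(res1.effects, res2.effects):
            assert e1.partial_eta_sq == pytest.approx(e2.partial_eta_sq, rel=1e-9)
            assert e1.f_value == pytest.approx(e2.f_value, rel=1e-9)

    def test_null_type_one_error_rate(self):
        """Under identical condition means with compound-symmetric noise the
        treatment F test rejects at close to the nominal 5% rate."""
        rng = np.random.default_rng(2024)
        n, m, sims = 14, 3, 500
        rejections = 0
        for _ in range(sims):
            subj = rng.normal(0, 1.0, size=(n, 1))
            y = (subj + rng.normal(0, 1.0, size=(n, m)))[:, :, None]
            res = RepeatedMeasuresAnova(long_format(y), "y", within="A").fit()
            if res.effect("A").p_value < 0.05:
                rejections += 1
        rate = rejections / sims
        assert 0.035 <= rate <= 0.065

    def test_posthoc_tukey_runs_on_significant_omnibus(self):
        rng = np.random.default_rng(6)
        n = 14
        y = rng.normal(0, 0.5, size=(n, 3, 1))
        y[:, 2, 0] += 2.0
        res = RepeatedMeasuresAnova(long_format(y), "y", within="A").fit()
        ph = res.posthoc_tukey()
        assert len(ph) == 3
        sig = ph[(ph.A == "a0") & (ph.B == "a2") | (ph.A == "a2") & (ph.B == "a0")]
        assert (sig.p_tukey < 0.05).all()
        # null omnibus: empty post-hoc by default
        y0 = rng.normal(size=(n, 3, 1))
        res0 = RepeatedMeasuresAnova(long_format(y0), "y", within="A").fit()
        if res0.effect("A").p_value >= 0.05:
            assert len(res0.posthoc_tukey()) == 0


class TestShapiroGate:
    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            shapiro_gate([[1.0, 1.0, 1.0, 1.0]])

    def test_tiny_cell_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            shapiro_gate([[1.0, 2.0]])

    def test_normal_data_routes_to_anova(self):
        """Type-I error of the gate: large normal cells pass ≥ 94% of runs."""
        rng = np.random.default_rng(10)
        passed = sum(
            shapiro_gate([rng.normal(size=5000)]) == "normal" for _ in range(100)
        )
        assert passed >= 94

    def test_exponential_data_routes_to_kruskal(self):
        rng = np.random.default_rng(11)
        caught = sum(
            shapiro_gate([rng.exponential(size=50)]) == "non_normal"
            for _ in range(100)
        )
        assert caught >= 90


class TestKruskal:
    def test_identical_groups_give_zero_h(self):
        h, p = kruskal_fallback([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_toy_groups_match_rank_formula(self):
        """{1,2,3} vs {4,5,6} vs {7,8,9}: mean ranks 2/5/8 give H = 7.2."""
        h, _ = kruskal_fallback([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, rel=1e-12)

    def test_power_against_shifted_groups(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(200):
            g1 = rng.normal(0, 1, 30)
            g2 = rng.normal(1, 1, 30)
            if kruskal_fallback([g1, g2])[1] < 0.05:
                rejections += 1
        assert rejections / 200 > 0.8

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            kruskal_fallback([[2.0, 2.0], [2.0, 2.0]])


class TestDeltas:
    def test_reference_maps_to_zero(self):
        t = pd.DataFrame({"condition": ["PP", "PC"] * 3, "y": [1, 2] * 3})
        d = deltas(t, "y")
        assert d["PP"] == 0.0
        assert d["PC"] == pytest.approx(1.0)

    def test_unknown_reference_rejected(self):
        t = pd.DataFrame({"condition": ["A", "B"], "y": [1, 2]})
        with pytest.raises(ValueError, match="unknown"):
            deltas(t, "y", reference="PP")


class TestPower:
    def test_published_sample_sizes(self):
        assert rm_sample_size(PowerQuery(effect_size_f=0.36)) == 14
        assert rm_sample_size(PowerQuery(effect_size_f=0.41)) == 12

    def test_power_monotone_in_n_and_f(self):
        q = PowerQuery(effect_size_f=0.3)
        powers = [rm_anova_power(n, q) for n in range(3, 40)]
        assert np.all(np.diff(powers) > 0)
        by_f = [
            rm_anova_power(12, PowerQuery(effect_size_f=f))
            for f in (0.2, 0.3, 0.4, 0.5)
        ]
        assert np.all(np.diff(by_f) > 0)

    def test_sample_size_nonincreasing_in_f(self):
        ns = [rm_sample_size(PowerQuery(effect_size_f=f))
              for f in (0.25, 0.36, 0.41, 0.6)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            rm_sample_size(PowerQuery(effect_size_f=0.0))

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            PowerQuery(effect_size_f=0.3, alpha=1.5)
        with pytest.raises(ValueError):
            PowerQuery(effect_size_f=0.3, n_measurements=1)
        with pytest.raises(ValueError):
            PowerQuery(effect_size_f=0.3, corr_among_measures=1.0)
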