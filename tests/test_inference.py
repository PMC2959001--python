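"""Statistical battery: rank test, log-scale GLM, eta^2, trend models."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from operant_iiv import (among_sessions_model, glm_log_pd, kruskal_wallis,
                         strain_comparison, variance_proportion,
                         within_sessions_model)
from operant_iiv.inference import (AmongSessionsTrend,
                                   StrainDispersionComparison,
                                   WithinSessionsTrend)


def hand_kruskal(groups):
    """Independent oracle: midranks + tie-corrected H from the textbook formula."""
    pooled = np.concatenate(groups)
    ranks = st.rankdata(pooled)
    N = pooled.size
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        start += g.size
        H += g.size * (r.mean() - (N + 1) / 2) ** 2
    H *= 12 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie


def pd_records(values_by_strain, n_sessions=1, trait="inattention"):
    """Build a PD table with given per-rat values (constant over sessions)."""
    rows = []
    for strain, vals in values_by_strain.items():
        for i, v in enumerate(vals):
            for s in range(1, n_sessions + 1):
                rows.append((f"{strain}{i}", strain, s, trait, v, v))
    return pd.DataFrame(rows, columns=["rat_id", "strain", "session",
                                       "trait", "pd", "session_mean"])


class TestKruskalWallis:
    def test_hand_derivable_value(self):
        H, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert H == pytest.approx(3.857, abs=5e-4)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_constants_give_zero(self):
        H, p = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert H == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis({"a": [1.0], "b": []})
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis({"a": [1.0]})

    def test_matches_hand_formula_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 8, size=12).astype(float)  # many ties
            b = rng.integers(2, 10, size=9).astype(float)
            H, _ = kruskal_wallis({"a": a, "b": b})
            assert H == pytest.approx(hand_kruskal([a, b]), rel=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=16), rng.normal(0.5, 1, size=15)
        H0, _ = kruskal_wallis({"a": a, "b": b})
        for f in (np.exp, lambda x: x**3, lambda x: np.arctan(x) * 5 + 1):
            H1, _ = kruskal_wallis({"a": f(a), "b": f(b)})
            assert H1 == pytest.approx(H0, rel=1e-12)

    def test_two_group_h_equals_squared_ranksum_z(self):
        """Tie-free two-group H equals the normal-approximation Wilcoxon
        rank-sum z statistic squared."""
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        H, _ = kruskal_wallis({"a": a, "b": b})
        n1, n2 = a.size, b.size
        w = st.rankdata(np.concatenate([a, b]))[:n1].sum()
        z = (w - n1 * (n1 + n2 + 1) / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert H == pytest.approx(z**2, rel=1e-10)


class TestGlmLogPd:
    def test_identical_groups_give_zero_f(self):
        rec = pd_records({"SHR": [1, 2, 3], "WKY": [1, 2, 3]})
        F, p, means = glm_log_pd(rec, "inattention")
        assert F == pytest.approx(0.0, abs=1e-12)
        assert means["SHR"][0] == pytest.approx(means["WKY"][0])

    def test_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(7)
        rec = pd_records({"SHR": rng.lognormal(1, 0.5, 16),
                          "WKY": rng.lognormal(0.5, 0.5, 15)})
        F, p, _ = glm_log_pd(rec, "inattention")
        per_rat = np.log(rec.groupby(["rat_id", "strain"])["pd"].mean() + 1.0)
        a = per_rat.xs("SHR", level="strain").to_numpy()
        b = per_rat.xs("WKY", level="strain").to_numpy()
        t, tp = st.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(tp, rel=1e-10)

    def test_invariant_to_row_order_and_rat_labels(self):
        rng = np.random.default_rng(8)
        rec = pd_records({"SHR": rng.lognormal(1, 0.5, 8),
                          "WKY": rng.lognormal(0.5, 0.5, 7)}, n_sessions=3)
        F0, p0, m0 = glm_log_pd(rec, "inattention")
        shuffled = rec.sample(frac=1, random_state=0).reset_index(drop=True)
        shuffled["rat_id"] = "x" + shuffled["rat_id"]
        F1, p1, m1 = glm_log_pd(shuffled, "inattention")
        assert F1 == pytest.approx(F0) and p1 == pytest.approx(p0)
        assert m1["SHR"][0] == pytest.approx(m0["SHR"][0])

    def test_single_rat_strain_rejected(self):
        rec = pd_records({"SHR": [1.0], "WKY": [1, 2, 3]})
        with pytest.raises(ValueError, match="fewer than 2"):
            glm_log_pd(rec, "inattention")

    def test_known_shift_recovery(self):
        """200 replicates of a 0.5 log-mean shift at n=16/15: the mean
        estimated group difference lands within 10% of the truth."""
        rng = np.random.default_rng(9)
        delta = 0.5
        diffs = []
        for _ in range(200):
            ya = rng.normal(1.0 + delta, 0.3, 16)
            yb = rng.normal(1.0, 0.3, 15)
            rec = pd_records({"SHR": np.exp(ya) - 1.0, "WKY": np.exp(yb) - 1.0})
            _, _, means = glm_log_pd(rec, "inattention")
            diffs.append(means["SHR"][0] - means["WKY"][0])
        assert np.mean(diffs) == pytest.approx(delta, rel=0.10)


class TestVarianceProportion:
    def test_all_between_group_variance(self):
        rec = pd_records({"SHR": [2, 2, 2], "WKY": [5, 5, 5]})
        assert variance_proportion(rec, "inattention") == pytest.approx(1.0)

    def test_pooled_constant_warns_and_returns_zero(self):
        rec = pd_records({"SHR": [3, 3], "WKY": [3, 3]})
        with pytest.warns(UserWarning, match="zero total variance"):
            assert variance_proportion(rec, "inattention") == 0.0

    def test_matches_brute_force_and_f_relation(self):
        rng = np.random.default_rng(10)
        rec = pd_records({"SHR": rng.lognormal(1, 0.4, 16),
                          "WKY": rng.lognormal(0.7, 0.4, 15)})
        eta2 = variance_proportion(rec, "inattention")
        y = np.log(rec.groupby(["rat_id", "strain"])["pd"].mean() + 1.0)
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2
                   for _, g in y.groupby(level="strain"))
        assert eta2 == pytest.approx(ss_b / ss_total, rel=1e-12)
        # eta^2 = F / (F + N - 2) for a two-group one-way model
        F, _, _ = glm_log_pd(rec, "inattention")
        assert eta2 == pytest.approx(F / (F + 31 - 2), rel=1e-10)


class TestStrainComparison:
    def test_units_and_report_fields(self):
        rng = np.random.default_rng(11)
        rec = pd_records({"SHR": rng.lognormal(1, 0.4, 6),
                          "WKY": rng.lognormal(0.4, 0.4, 5)}, n_sessions=3)
        r = strain_comparison(rec, "inattention", kw_unit="rat")
        assert 0 <= r.kw_p <= 1 and 0 <= r.variance_proportion <= 1
        r2 = strain_comparison(rec, "inattention", kw_unit="rat-session")
        assert r2.kw_unit == "rat-session"
        with pytest.raises(ValueError):
            strain_comparison(rec, "inattention", kw_unit="bogus")

    def test_estimator_table_layout(self):
        rng = np.random.default_rng(12)
        frames = [pd_records({"SHR": rng.lognormal(1, 0.4, 6),
                              "WKY": rng.lognormal(0.4, 0.4, 5)}, trait=t)
                  for t in ("hyperactivity", "impulsiveness", "inattention")]
        est = StrainDispersionComparison().fit(pd.concat(frames))
        tab = est.comparison_table_
        assert tab["trait"].tolist() == ["hyperactivity", "impulsiveness",
                                         "inattention"]
        assert {"kw_chi2", "kw_p", "glm_F", "glm_p", "eta2",
                "mean_log_SHR", "ci95_halfwidth_WKY"} <= set(tab.columns)


def trend_records(rng, n_a=6, n_b=5, n_sessions=5, shift_b=0.0, trait="inattention"):
    rows = []
    for strain, n, shift in (("SHR", n_a, 0.0), ("WKY", n_b, shift_b)):
        for i in range(n):
            base = rng.normal(2.0, 0.3)
            for s in range(1, n_sessions + 1):
                v = np.exp(base + shift + rng.normal(0, 0.2)) - 1.0
                rows.append((f"{strain}{i}", strain, s, trait, max(v, 0.0), v))
    return pd.DataFrame(rows, columns=["rat_id", "strain", "session",
                                       "trait", "pd", "session_mean"])


class TestAmongSessionsModel:
    def test_constant_shift_moves_only_the_strain_effect(self):
        """Adding a constant to one strain's (log-scale) values changes the
        strain p-value but not the session or interaction p-values."""
        rng = np.random.default_rng(13)
        rec0 = trend_records(rng)
        rec1 = rec0.copy()
        mask = rec1["strain"] == "WKY"
        # +1 on the log scale: log(pd+1) + 1 = log((pd+1)*e - 1 + 1)
        rec1.loc[mask, "pd"] = (rec1.loc[mask, "pd"] + 1.0) * np.e - 1.0
        f0 = among_sessions_model(rec0, "inattention")
        f1 = among_sessions_model(rec1, "inattention")
        assert f1.effect_p_values["index"] == pytest.approx(
            f0.effect_p_values["index"], rel=1e-6)
        assert f1.effect_p_values["interaction"] == pytest.approx(
            f0.effect_p_values["interaction"], rel=1e-6)
        assert f1.effect_p_values["group"] != pytest.approx(
            f0.effect_p_values["group"], rel=1e-3)

    def test_unbalanced_sessions_rejected(self):
        rec = trend_records(np.random.default_rng(14))
        rec = rec.drop(rec[(rec["rat_id"] == "SHR0") & (rec["session"] == 3)].index)
        with pytest.raises(ValueError, match="unbalanced"):
            among_sessions_model(rec, "inattention")

    def test_estimator_front_end(self):
        rec = trend_records(np.random.default_rng(15))
        est = AmongSessionsTrend().fit(rec)
        fit = est.fits_["inattention"]
        assert fit.scope == "among_sessions"
        assert set(fit.effect_p_values) == {"group", "index", "interaction"}
        assert set(fit.slope_by_strain) == {"SHR", "WKY"}


def segdev_table(values_by_rat, trait="inattention"):
    rows = []
    for (rat, strain), vals in values_by_rat.items():
        for k, v in enumerate(vals, start=1):
            rows.append((rat, strain, trait, k, v))
    return pd.DataFrame(rows, columns=["rat_id", "strain", "trait",
                                       "segment", "mean_abs_dev"])


class TestWithinSessionsModel:
    def test_exact_linear_input_is_degenerate(self):
        """Every rat with deviations exactly (1..5): slope 1 per segment on
        the raw scale, SE 0 flagged as degenerate."""
        vals = {(f"SHR{i}", "SHR"): [1, 2, 3, 4, 5] for i in range(3)}
        vals.update({(f"WKY{i}", "WKY"): [1, 2, 3, 4, 5] for i in range(3)})
        with pytest.warns(UserWarning, match="degenerate"):
            fit = within_sessions_model(segdev_table(vals), "inattention")
        for strain in ("SHR", "WKY"):
            beta, se = fit.slope_by_strain[strain]
            assert beta == pytest.approx(1.0, abs=1e-10)
            assert se == 0.0
        assert set(fit.degenerate_strains) == {"SHR", "WKY"}
        assert fit.pooled_slope[0] == pytest.approx(1.0, abs=1e-10)

    def test_slope_scale_option(self):
        rng = np.random.default_rng(16)
        vals = {(f"SHR{i}", "SHR"): np.exp(0.3 * np.arange(5) + rng.normal(0, .05, 5))
                for i in range(4)}
        vals.update({(f"WKY{i}", "WKY"): np.exp(rng.normal(0, .05, 5))
                     for i in range(4)})
        raw = within_sessions_model(segdev_table(vals), "inattention",
                                    slope_scale="raw")
        logf = within_sessions_model(segdev_table(vals), "inattention",
                                     slope_scale="log")
        assert raw.slope_scale == "raw" and logf.slope_scale == "log"
        assert raw.slope_by_strain["SHR"][0] > 0
        assert logf.slope_by_strain["SHR"][0] > 0
        with pytest.raises(ValueError):
            within_sessions_model(segdev_table(vals), "inattention",
                                  slope_scale="bogus")

    def test_estimator_front_end(self):
        rng = np.random.default_rng(17)
        vals = {(f"SHR{i}", "SHR"): rng.lognormal(0, 0.3, 5) for i in range(4)}
        vals.update({(f"WKY{i}", "WKY"): rng.lognormal(0, 0.3, 5)
                     for i in range(4)})
        est = WithinSessionsTrend().fit(segdev_table(vals))
        assert est.fits_["inattention"].scope == "within_sessions"
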