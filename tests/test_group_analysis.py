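"""Valence bias, ANOVA, correlations, and posterior predictive checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import looplearn as ll


# ---------------------------------------------------------------------------
# valence bias score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pos, neg, expected",
    [(0.1, 0.1, 0.0), (0.2, 0.0, 1.0), (0.09, 0.15, -0.25)],
)
def test_valence_bias_examples(pos, neg, expected):
    assert ll.valence_bias_score(pos, neg) == pytest.approx(expected, abs=1e-12)


def test_valence_bias_undefined_when_both_zero():
    with pytest.warns(UserWarning):
        assert np.isnan(ll.valence_bias_score(0.0, 0.0))


def test_valence_bias_rejects_negative_rates():
    with pytest.raises(ValueError):
        ll.valence_bias_score(-0.1, 0.2)


@given(
    pos=st.floats(0.001, 1), neg=st.floats(0.001, 1), c=st.floats(0.01, 100)
)
@settings(max_examples=200, deadline=None)
def test_valence_bias_scale_invariant_and_odd(pos, neg, c):
    base = ll.valence_bias_score(pos, neg)
    assert ll.valence_bias_score(c * pos, c * neg) == pytest.approx(base, rel=1e-9)
    assert ll.valence_bias_score(neg, pos) == pytest.approx(-base, rel=1e-9)
    assert -1.0 <= base <= 1.0


def test_valence_bias_table_flags_undefined():
    rates = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "alpha_pos_self": [0.1, 0.0],
            "alpha_neg_self": [0.2, 0.0],
        }
    )
    with pytest.warns(UserWarning):
        scores = ll.valence_bias_table(rates)
    assert scores["a"] == pytest.approx(-1 / 3)
    assert np.isnan(scores["b"])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _toy_2x2():
    # 4 subjects x Agent(2) x Valence(2)
    rows = []
    vals = {
        ("s1", "self", "pos"): 0.10, ("s1", "self", "neg"): 0.20,
        ("s1", "other", "pos"): 0.12, ("s1", "other", "neg"): 0.11,
        ("s2", "self", "pos"): 0.15, ("s2", "self", "neg"): 0.22,
        ("s2", "other", "pos"): 0.13, ("s2", "other", "neg"): 0.15,
        ("s3", "self", "pos"): 0.08, ("s3", "self", "neg"): 0.16,
        ("s3", "other", "pos"): 0.10, ("s3", "other", "neg"): 0.09,
        ("s4", "self", "pos"): 0.12, ("s4", "self", "neg"): 0.25,
        ("s4", "other", "pos"): 0.14, ("s4", "other", "neg"): 0.13,
    }
    for (s, a, v), y in vals.items():
        rows.append({"subject": s, "agent": a, "valence": v, "y": y})
    return pd.DataFrame(rows)


def _hand_ss_2x2(df):
    """Sums-of-squares decomposition written out with explicit means."""
    wide = df.pivot_table(index="subject", columns=["agent", "valence"], values="y")
    grand = wide.to_numpy().mean()
    subj = wide.mean(axis=1)
    m_agent = df.groupby("agent")["y"].mean()
    m_val = df.groupby("valence")["y"].mean()
    m_cell = df.groupby(["agent", "valence"])["y"].mean()
    ss_agent = 8 * sum((m_agent[a] - grand) ** 2 for a in ("self", "other"))
    ss_val = 8 * sum((m_val[v] - grand) ** 2 for v in ("pos", "neg"))
    ss_int = 4 * sum(
        (m_cell[a, v] - m_agent[a] - m_val[v] + grand) ** 2
        for a in ("self", "other") for v in ("pos", "neg")
    )
    err = {}
    for name, factor, m_f in [
        ("agent", "agent", m_agent), ("valence", "valence", m_val)
    ]:
        tot = 0.0
        for s in wide.index:
            for lev in df[factor].unique():
                y_sl = df[(df.subject == s) & (df[factor] == lev)]["y"].mean()
                tot += (y_sl - m_f[lev] - subj[s] + grand) ** 2
        err[name] = 2 * tot
    # interaction error: residual of the full decomposition
    tot = 0.0
    for s in wide.index:
        for a in ("self", "other"):
            for v in ("pos", "neg"):
                y = df[(df.subject == s) & (df.agent == a) & (df.valence == v)][
                    "y"
                ].iloc[0]
                y_sa = df[(df.subject == s) & (df.agent == a)]["y"].mean()
                y_sv = df[(df.subject == s) & (df.valence == v)]["y"].mean()
                tot += (
                    y - m_cell[a, v] - y_sa - y_sv + m_agent[a] + m_val[v] + subj[s]
                    - grand
                ) ** 2
    err["interaction"] = tot
    f_agent = (ss_agent / 1) / (err["agent"] / 3)
    f_val = (ss_val / 1) / (err["valence"] / 3)
    f_int = (ss_int / 1) / (err["interaction"] / 3)
    return f_agent, f_val, f_int


def test_rm_anova_matches_hand_computed_toy_table():
    df = _toy_2x2()
    table = ll.rm_anova(df, dv="y", within=["agent", "valence"], subject="subject")
    f_agent, f_val, f_int = _hand_ss_2x2(df)
    got = table.set_index("effect")
    assert got.loc["agent", "F"] == pytest.approx(f_agent, rel=1e-9)
    assert got.loc["valence", "F"] == pytest.approx(f_val, rel=1e-9)
    assert got.loc["agent x valence", "F"] == pytest.approx(f_int, rel=1e-9)
    assert (got["df1"] == 1).all() and (got["df2"] == 3).all()


def test_rm_anova_matches_pingouin_two_way():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    rows = [
        {"subject": f"s{i}", "a": a, "b": b, "y": rng.normal()}
        for i in range(10) for a in ("a1", "a2") for b in ("b1", "b2", "b3")
    ]
    df = pd.DataFrame(rows)
    ours = ll.rm_anova(df, dv="y", within=["a", "b"], subject="subject")
    theirs = pg.rm_anova(
        data=df, dv="y", within=["a", "b"], subject="subject", detailed=True
    )
    ours = ours.set_index("effect")
    for eff_pg, eff_ours in [("a", "a"), ("b", "b"), ("a * b", "a x b")]:
        row = theirs[theirs["Source"] == eff_pg].iloc[0]
        assert ours.loc[eff_ours, "F"] == pytest.approx(row["F"], rel=1e-6)
        assert ours.loc[eff_ours, "p"] == pytest.approx(row["p_unc"], rel=1e-6)


def test_rm_anova_matches_pingouin_mixed_design():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    rows = []
    for i in range(12):
        grp = "g1" if i < 6 else "g2"
        base = rng.normal()
        for w in ("w1", "w2"):
            rows.append(
                {
                    "subject": f"s{i}", "group": grp, "w": w,
                    "y": base + rng.normal() + (0.5 if (grp, w) == ("g2", "w2") else 0),
                }
            )
    df = pd.DataFrame(rows)
    ours = ll.rm_anova(
        df, dv="y", within=["w"], subject="subject", between="group"
    ).set_index("effect")
    theirs = pg.mixed_anova(
        data=df, dv="y", within="w", subject="subject", between="group"
    ).set_index("Source")
    assert ours.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"], rel=1e-6)
    assert ours.loc["w", "F"] == pytest.approx(theirs.loc["w", "F"], rel=1e-6)
    assert ours.loc["w x group", "F"] == pytest.approx(
        theirs.loc["Interaction", "F"], rel=1e-6
    )


def test_rm_anova_constant_data_gives_zero_f():
    df = _toy_2x2().assign(y=0.5)
    table = ll.rm_anova(df, dv="y", within=["agent", "valence"], subject="subject")
    assert (table["F"] == 0.0).all()
    assert (table["p"] == 1.0).all()


def test_rm_anova_location_invariance_of_interaction():
    df = _toy_2x2()
    t1 = ll.rm_anova(df, dv="y", within=["agent", "valence"], subject="subject")
    df2 = df.assign(y=df["y"] + 100.0)
    t2 = ll.rm_anova(df2, dv="y", within=["agent", "valence"], subject="subject")
    i1 = t1.set_index("effect").loc["agent x valence", "F"]
    i2 = t2.set_index("effect").loc["agent x valence", "F"]
    assert i1 == pytest.approx(i2, rel=1e-9)


def test_rm_anova_missing_cell_raises():
    df = _toy_2x2().iloc[:-1]
    with pytest.raises(ValueError):
        ll.rm_anova(df, dv="y", within=["agent", "valence"], subject="subject")


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_partial_corr_reduces_to_pearson_without_controls():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=50), rng.normal(size=50)
    from scipy.stats import pearsonr

    r, p = ll.partial_corr(x, y)
    r2, p2 = pearsonr(x, y)
    assert r == pytest.approx(r2, abs=1e-12)
    assert p == pytest.approx(p2, abs=1e-12)


def test_partial_corr_matches_residual_regression_oracle():
    x = np.array([1.0, 2.0, 3.3, 4.1, 5.7, 6.2])
    y = np.array([2.1, 2.0, 3.9, 4.4, 5.1, 7.0])
    z = np.array([0.5, 1.4, 1.1, 2.9, 2.2, 3.5])
    r, _ = ll.partial_corr(x, y, z)
    # two-stage regression done with polyfit as an independent path
    rx = x - np.polyval(np.polyfit(z, x, 1), z)
    ry = y - np.polyval(np.polyfit(z, y, 1), z)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert r == pytest.approx(oracle, abs=1e-10)


def test_partial_corr_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    n = 40
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = 0.5 * z + rng.normal(size=n)
    r, p = ll.partial_corr(x, y, z)
    out = pg.partial_corr(
        data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
    )
    assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
    assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-9)


def test_partial_corr_degenerate_and_invalid():
    rng = np.random.default_rng(1)
    z = rng.normal(size=20)
    x = rng.normal(size=20)
    with pytest.warns(UserWarning):
        r, p = ll.partial_corr(x, z.copy(), z)
    assert r == 0.0
    with pytest.raises(ValueError):
        ll.partial_corr(x, z, np.column_stack([z, 2 * z]))


def test_fisher_z_equal_correlations():
    z, p = ll.fisher_z_compare(0.3, 30, 0.3, 50)
    assert z == 0.0 and p == pytest.approx(1.0)


def test_fisher_z_antisymmetric():
    z1, p1 = ll.fisher_z_compare(0.5, 40, 0.1, 35)
    z2, p2 = ll.fisher_z_compare(0.1, 35, 0.5, 40)
    assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)


def test_fisher_z_private_vs_public_magnitude():
    """The private-group (r=0.06, n=52) vs public-group (r=-0.39, n=60)
    contrast lands near the reported z ~= 2.4."""
    z, p = ll.fisher_z_compare(0.06, 52, -0.39, 60)
    assert 2.2 <= abs(z) <= 2.6
    assert p < 0.05


def test_fisher_z_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        ll.fisher_z_compare(1.0, 30, 0.2, 30)
    with pytest.raises(ValueError):
        ll.fisher_z_compare(0.5, 3, 0.2, 30)


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def test_ppc_near_perfect_for_noiseless_data(quick_cfg):
    m3 = ll.get_model("audience_private", "M3_valence")
    design = ll.build_design("audience_private", seed=6)
    params = ll.ParameterSet(alphas=[0.1, 0.2], init_values=[55.0, 45.0], noise_sd=1.0)
    data = ll.simulate_subject(design, m3, params, seed=3, subject_id="s1")
    fits = {"s1": {"M3_valence": ll.fit_subject(m3, data, quick_cfg)}}
    report = ll.ppc(fits, [data], m3)
    assert report.overall_r2["s1"] > 0.95


def test_ppc_flags_constant_predictions(quick_cfg):
    mm = ll.get_model("audience_private", "M_mean")
    design = ll.build_design("audience_private", seed=6)
    params = ll.ParameterSet(condition_means=[50.0, 50.0], noise_sd=8.0)
    data = ll.simulate_subject(design, mm, params, seed=3, subject_id="s1")
    fits = {"s1": {"M_mean": ll.fit_subject(mm, data, quick_cfg)}}
    with pytest.warns(UserWarning):
        report = ll.ppc(fits, [data], mm)
    # per-condition predictions are constant -> degenerate R^2 is flagged
    per_cond = report.per_subject[report.per_subject.condition != "overall"]
    assert per_cond["r2"].isna().all()


def test_ppc_cohort_r2_in_plausible_band(quick_cfg):
    """At the task's noise level the winning model explains a moderate
    share of rating variance, not all of it."""
    cohort = ll.simulate_cohort(6, "audience_private", seed=17)
    m3 = ll.get_model("audience_private", "M3_valence")
    fits = ll.fit_cohort(cohort.datasets, [m3], quick_cfg)
    report = ll.ppc(fits, cohort.datasets, m3)
    mean_r2 = report.overall_r2.mean()
    assert 0.2 <= mean_r2 <= 0.8
    anova = report.anova_predicted.set_index("effect")
    assert anova.loc["ability", "F"] > 10  # predictions separate the conditions


def test_model_free_anova_detects_learning():
    cohort = ll.simulate_cohort(8, "audience_private", seed=19)
    frames = []
    for d in cohort.datasets:
        df = d.design.to_frame()
        df.insert(0, "subject_id", d.subject_id)
        df["observed"] = d.exp_ratings
        df["cond_trial"] = df.groupby(["agent", "ability"]).cumcount() + 1
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    table = ll.model_free_anova(trials).set_index("effect")
    # learners separate the ability conditions and adapt over trials
    assert table.loc["ability", "p"] < 0.01
    assert table.loc["cond_trial x ability", "p"] < 0.05
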