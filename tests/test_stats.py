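"""Repeated-measures ANOVA, paired t with JZS Bayes factor, within-subject SEM."""

import numpy as np
import pandas as pd
import pytest

from cueddm import jzs_bf10, paired_t, rm_anova_2x2, within_subject_sem


def _long_table(y):
    """y: (n, 2, 2) array indexed [subject, space, feature] -> long format."""
    n = y.shape[0]
    rows = []
    for i in range(n):
        for ai, sv in enumerate([False, True]):
            for bi, fv in enumerate([False, True]):
                rows.append(
                    {
                        "subject_id": i,
                        "space_valid": sv,
                        "feature_valid": fv,
                        "y": y[i, ai, bi],
                    }
                )
    return pd.DataFrame(rows)


def _brute_force_ss(y):
    """Independent sums-of-squares oracle via explicit model-comparison loops."""
    n = y.shape[0]
    g = y.mean()
    ss = {}
    ss["subj"] = sum(4 * (y[i].mean() - g) ** 2 for i in range(n))
    ss["A"] = sum(2 * n * (y[:, a, :].mean() - g) ** 2 for a in range(2))
    ss["B"] = sum(2 * n * (y[:, :, b].mean() - g) ** 2 for b in range(2))
    ss["AB"] = sum(
        n * (y[:, a, b].mean() - y[:, a, :].mean() - y[:, :, b].mean() + g) ** 2
        for a in range(2)
        for b in range(2)
    )
    ss["AS"] = sum(
        2 * (y[i, a, :].mean() - y[i].mean() - y[:, a, :].mean() + g) ** 2
        for i in range(n)
        for a in range(2)
    )
    ss["BS"] = sum(
        2 * (y[i, :, b].mean() - y[i].mean() - y[:, :, b].mean() + g) ** 2
        for i in range(n)
        for b in range(2)
    )
    ss["total"] = ((y - g) ** 2).sum()
    ss["ABS"] = (
        ss["total"] - ss["subj"] - ss["A"] - ss["B"] - ss["AB"] - ss["AS"] - ss["BS"]
    )
    return ss


def test_anova_matches_brute_force_oracle():
    rng = np.random.default_rng(21)
    y = rng.normal(size=(5, 2, 2)) + rng.normal(size=(5, 1, 1))
    ss = _brute_force_ss(y)
    res = {r.effect: r for r in rm_anova_2x2(_long_table(y), "y")}
    n = 5
    assert res["space"].F == pytest.approx(ss["A"] / (ss["AS"] / (n - 1)), rel=1e-10)
    assert res["feature"].F == pytest.approx(ss["B"] / (ss["BS"] / (n - 1)), rel=1e-10)
    assert res["interaction"].F == pytest.approx(
        ss["AB"] / (ss["ABS"] / (n - 1)), rel=1e-9
    )
    err = ss["subj"] + ss["AS"] + ss["BS"] + ss["ABS"]
    assert res["space"].eta_g2 == pytest.approx(ss["A"] / (ss["A"] + err), rel=1e-10)
    assert res["space"].df1 == 1 and res["space"].df2 == 4


def test_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(22)
    y = rng.normal(size=(12, 2, 2))
    y[:, 1, :] += 0.4  # space effect
    table = _long_table(y)
    ours = {r.effect: r for r in rm_anova_2x2(table, "y")}
    ref = pg.rm_anova(
        data=table,
        dv="y",
        within=["space_valid", "feature_valid"],
        subject="subject_id",
        detailed=True,
        effsize="ng2",
    ).set_index("Source")
    assert ours["space"].F == pytest.approx(ref.loc["space_valid", "F"], rel=1e-8)
    assert ours["feature"].F == pytest.approx(ref.loc["feature_valid", "F"], rel=1e-8)
    assert ours["interaction"].F == pytest.approx(
        ref.loc["space_valid * feature_valid", "F"], rel=1e-8
    )
    assert ours["space"].p == pytest.approx(ref.loc["space_valid", "p_unc"], rel=1e-8)
    assert ours["space"].eta_g2 == pytest.approx(ref.loc["space_valid", "ng2"], rel=1e-8)


def test_anova_zero_for_identical_cells():
    y = np.tile(np.arange(6)[:, None, None], (1, 2, 2)).astype(float)
    for r in rm_anova_2x2(_long_table(y), "y"):
        assert r.F == pytest.approx(0.0, abs=1e-20)


def test_anova_rejects_missing_cells():
    y = np.random.default_rng(0).normal(size=(4, 2, 2))
    table = _long_table(y).iloc[:-1]
    with pytest.raises(ValueError, match="incomplete"):
        rm_anova_2x2(table, "y")


def test_f_equals_squared_paired_t_on_marginals():
    rng = np.random.default_rng(23)
    y = rng.normal(size=(10, 2, 2))
    res = {r.effect: r for r in rm_anova_2x2(_long_table(y), "y")}
    t_space = paired_t(y[:, 1, :].mean(axis=1), y[:, 0, :].mean(axis=1))
    assert res["space"].F == pytest.approx(t_space.t**2, rel=1e-10)
    assert res["space"].p == pytest.approx(t_space.p, rel=1e-10)


def test_paired_t_closed_form():
    # differences with mean 1, sd 1, n = 31: t = sqrt(31), dz = 1
    rng = np.random.default_rng(24)
    d = rng.normal(size=31)
    d = (d - d.mean()) / d.std(ddof=1) + 1.0
    res = paired_t(d, np.zeros(31))
    assert res.t == pytest.approx(np.sqrt(31), rel=1e-12)
    assert res.dz == pytest.approx(1.0, rel=1e-12)
    assert res.df == 30


def test_paired_t_identical_vectors_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_null_t_gives_evidence_for_null():
    x = np.array([0.3, -0.1, 0.2, -0.4, 0.0, 0.1])
    res = paired_t(x, np.full_like(x, x.mean()))
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.bf10 < 1


def test_jzs_bf_matches_independent_oracle():
    pg = pytest.importorskip("pingouin")
    for t, n in [(0.0, 30), (1.5, 12), (2.5, 31), (5.23, 31), (-2.0, 20)]:
        ours = jzs_bf10(t, n)
        ref = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
        assert ours == pytest.approx(ref, rel=1e-4)


def test_bf_monotone_in_t_and_below_one_at_zero():
    bfs = [jzs_bf10(t, 25) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
    assert bfs[0] < 1


def test_within_sem_zero_for_pure_subject_offsets():
    offsets = np.array([1.0, 5.0, -2.0, 0.5])
    wide = pd.DataFrame({c: offsets for c in ("c1", "c2", "c3")})
    sems = within_subject_sem(wide)
    assert np.allclose(sems, 0.0)


def test_within_sem_hand_computation_k2():
    wide = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 3.0]})
    # normalized scores: x - row mean + grand mean (grand = 2.5)
    norm_a = np.array([1 - 1.5, 2 - 3, 3 - 3]) + 2.5
    expected = norm_a.std(ddof=1) / np.sqrt(3) * np.sqrt(2)  # Morey sqrt(k/(k-1))
    sems = within_subject_sem(wide)
    assert sems["a"] == pytest.approx(expected, rel=1e-12)
    assert sems["b"] == pytest.approx(expected, rel=1e-12)  # k=2 symmetry


def test_within_sem_invariant_to_subject_constants():
    rng = np.random.default_rng(25)
    wide = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
    shifted = wide.add(rng.normal(size=8) * 10, axis=0)
    pd.testing.assert_series_equal(
        within_subject_sem(wide), within_subject_sem(shifted)
    )


def test_within_sem_needs_two_conditions():
    with pytest.raises(ValueError):
        within_subject_sem(pd.DataFrame({"a": [1.0, 2.0]}))
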