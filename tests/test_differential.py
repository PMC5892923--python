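"""Fold-change conventions, the nested paired test, screening and SOI rules."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st

from digepipe.differential import (
    build_soi_set,
    call_significant,
    cross_patient_table,
    cross_patient_test,
    differential_table,
    lnfc_by_gel,
    per_patient_screen,
    select_variable,
    signed_fold_change,
)
from digepipe.normalize import average_replicates, ratiometric_normalize
from digepipe.simulate import SimulationConfig, simulate_study


@pytest.mark.parametrize(
    "h, l, expected",
    [(1.5, 1.0, 1.5), (1.0, 1.25, -1.25), (2.0, 2.0, 1.0), (9.0, 3.0, 3.0)],
)
def test_signed_fold_change_examples(h, l, expected):
    assert signed_fold_change(h, l) == pytest.approx(expected)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(h=st.floats(min_value=1e-3, max_value=1e3),
       l=st.floats(min_value=1e-3, max_value=1e3))
def test_signed_fold_change_antisymmetric(h, l):
    if h == l:
        assert signed_fold_change(h, l) == 1.0
    else:
        assert signed_fold_change(h, l) == pytest.approx(
            -signed_fold_change(l, h))
    assert abs(signed_fold_change(h, l)) >= 1.0


def test_signed_fold_change_rejects_nonpositive():
    with pytest.raises(Exception, match="positive"):
        signed_fold_change(0.0, 1.0)


def test_cross_patient_test_hand_computation():
    """Patient mean ln FCs (0.2, 0.3, 0.25, 0.28, 0.22, 0.31):
    t = mean/(sd/sqrt(6)), two-sided p from t with df=5."""
    values = {f"p{i}": [v] for i, v in
              enumerate([0.2, 0.3, 0.25, 0.28, 0.22, 0.31])}
    res = cross_patient_test(values)
    arr = np.array([0.2, 0.3, 0.25, 0.28, 0.22, 0.31])
    t_exp = arr.mean() / (arr.std(ddof=1) / math.sqrt(6))
    assert res.t == pytest.approx(t_exp)
    assert res.df == 5
    assert res.p == pytest.approx(2 * ss.t.sf(abs(t_exp), 5))
    assert res.fc == pytest.approx(math.exp(arr.mean()))


def test_cross_patient_test_symmetric_values_give_p_one():
    values = {f"p{i}": [v] for i, v in
              enumerate([-0.1, 0.1, -0.2, 0.2, -0.3, 0.3])}
    res = cross_patient_test(values)
    assert res.mean_lnfc == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_cross_patient_test_degenerate_zero_variance():
    res = cross_patient_test({"p1": [0.2], "p2": [0.2], "p3": [0.2]})
    assert res.degenerate
    assert math.isnan(res.p)


def test_balanced_shortcut_matches_reml_random_intercept():
    """The one-sample t on patient means equals a general REML
    random-intercept fit (statsmodels MixedLM) to <= 1e-6 in p."""
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    pat_eff = rng.normal(0.25, 0.12, 6)
    reps = {f"p{i}": [e + rng.normal(0, 0.05) for _ in range(2)]
            for i, e in enumerate(pat_eff)}
    short = cross_patient_test(reps)
    endog = np.concatenate([reps[k] for k in sorted(reps)])
    groups = np.repeat(np.arange(6), 2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(endog, np.ones_like(endog)[:, None],
                         groups=groups).fit(reml=True, method="powell",
                                            xtol=1e-12, ftol=1e-12,
                                            maxiter=5000)
    t_mixed = fit.params[0] / fit.bse[0]
    p_mixed = 2 * ss.t.sf(abs(t_mixed), 5)
    assert short.p == pytest.approx(p_mixed, abs=1e-6)


def test_dye_swap_relabelling_invariance():
    """Swapping which replicate gel is listed first changes nothing."""
    rng = np.random.default_rng(0)
    reps = {f"p{i}": list(rng.normal(0.1, 0.05, 2)) for i in range(6)}
    swapped = {k: v[::-1] for k, v in reps.items()}
    a, b = cross_patient_test(reps), cross_patient_test(swapped)
    assert (a.t, a.p, a.fc) == (b.t, b.p, b.fc)


def test_per_patient_screen_examples():
    cols = pd.MultiIndex.from_tuples(
        [("p1", "high", "g1"), ("p1", "high", "g2"),
         ("p1", "low", "g1"), ("p1", "low", "g2")],
        names=["patient", "condition", "gel_id"],
    )
    frame = pd.DataFrame(
        [
            [100.0, 100.0 + 1e-9, 50.0, 50.0 - 1e-9],  # FC +2, ~zero variance
            [100.0, 90.0, 95.0, 105.0],                # |FC| < 1.25
            [80.0, 80.0, 80.0, 80.0],                  # FC exactly 1
        ],
        index=["s1", "s2", "s3"],
        columns=cols,
    )
    calls = per_patient_screen(frame, anova_gate=True)
    assert calls.loc["s1", "p1"]
    assert not calls.loc["s2", "p1"]
    assert not calls.loc["s3", "p1"]


def test_per_patient_screen_warns_without_replicates():
    cols = pd.MultiIndex.from_tuples(
        [("p1", "high", "g1"), ("p1", "low", "g1")],
        names=["patient", "condition", "gel_id"],
    )
    frame = pd.DataFrame([[130.0, 100.0]], index=["s1"], columns=cols)
    with pytest.warns(UserWarning, match="ANOVA gate skipped"):
        calls = per_patient_screen(frame, anova_gate=True)
    assert calls.loc["s1", "p1"]


@pytest.mark.parametrize(
    "p, fc, expected",
    [(0.01, 1.4, True), (0.01, 1.1, False), (0.06, 2.0, False),
     (0.04, 1.25, True), (0.04, -1.3, True)],
)
def test_call_significant_rule(p, fc, expected):
    assert call_significant(p, fc) is expected


def test_select_variable_rule():
    screen = pd.DataFrame(
        {
            "s1": [True, True, True, False, False, False],
            "s2": [True, True, False, False, False, False],
            "s3": [True] * 6,
        },
        index=[f"p{i}" for i in range(6)],
    ).T
    variable = select_variable(screen)
    assert bool(variable["s1"]) and not bool(variable["s2"])
    assert bool(variable["s3"])


def test_build_soi_union_counts():
    def frame(n_sig, n_var, n_both, fraction):
        n = n_sig + n_var + n_both + 5
        sig = [True] * n_sig + [False] * n_var + [True] * n_both + [False] * 5
        var = [False] * n_sig + [True] * n_var + [True] * n_both + [False] * 5
        df = pd.DataFrame(
            {"fraction": fraction, "significant": sig, "variable": var},
            index=pd.Index([f"{fraction}-{i}" for i in range(n)],
                           name="spot_id"),
        )
        df["soi"] = df["significant"] | df["variable"]
        return df

    soi = build_soi_set([frame(10, 20, 5, "cytosol")])
    assert len(soi) == 35  # 10 sig-only + 20 var-only + 5 overlapping
    assert len(build_soi_set([])) == 0


def test_cross_patient_table_matches_scalar_api():
    rng = np.random.default_rng(3)
    cols = pd.MultiIndex.from_tuples(
        [(f"p{i}", f"g{i}{r}") for i in range(6) for r in range(2)],
        names=["patient", "gel_id"],
    )
    lnfc = pd.DataFrame(rng.normal(0.1, 0.2, size=(4, 12)), columns=cols,
                        index=[f"s{i}" for i in range(4)])
    table = cross_patient_table(lnfc)
    for spot in lnfc.index:
        per_patient = {p: lnfc.loc[spot, p].to_numpy()
                       for p in lnfc.columns.get_level_values(0).unique()}
        res = cross_patient_test(per_patient)
        assert table.loc[spot, "p"] == pytest.approx(res.p)
        assert table.loc[spot, "t"] == pytest.approx(res.t)


def test_lnfc_by_gel_uses_paired_channels(tiny_design):
    table = simulate_study(
        SimulationConfig(n_spots=20, fractions=("cytosol",), seed=8,
                         marker_panels=(), include_gfap=False,
                         n_differential=0)
    )
    channels = ratiometric_normalize(table.tables["cytosol"], table.design)
    lnfc = lnfc_by_gel(channels)
    # one column per (patient, gel): 6 patients x 2 dye-swap gels
    assert lnfc.shape == (20, 12)
    patient, gel = lnfc.columns[0]
    h = channels[(patient, "high", gel)]
    l = channels[(patient, "low", gel)]
    assert np.allclose(lnfc[(patient, gel)], np.log(h) - np.log(l))


def test_differential_table_flags_consistent(sim_default):
    study = sim_default
    channels = ratiometric_normalize(study.tables["cytosol"], study.design)
    expr = average_replicates(channels, study.design)
    diff = differential_table(channels, expr)
    assert ((diff["soi"] == (diff["significant"] | diff["variable"])).all())
    fc_cols = [c for c in diff.columns if c.startswith("fc_")]
    assert (diff[fc_cols].abs() >= 1.0).all().all()
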