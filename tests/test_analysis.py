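"""Analysis procedures: KRI, peaks, logistic fits, onset, Dunnett, labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kinsig import analysis, assays
from kinsig.analysis import (
    ConcentrationResponseModel,
    classify_surmountability,
    compute_ec80,
    compute_kri,
    compute_onset,
    dunnett_anova,
    fit_concentration_response,
    fit_inhibition,
    normalize_to_control,
    peak_response,
)
from kinsig.kinetics import ValidationError


# -- KRI ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "b1,b2,expected", [(100.0, 100.0, 1.0), (90.0, 50.0, 1.8), (35.0, 50.0, 0.7)]
)
def test_kri_is_binding_ratio(b1, b2, expected):
    res = compute_kri(b1, b2)
    assert res.kri == pytest.approx(expected)
    assert res.b_t1 == b1 and res.b_t2 == b2


def test_kri_interpretation_sign():
    assert "slower" in compute_kri(90, 50).interpretation
    assert "faster" in compute_kri(35, 50).interpretation


def test_kri_rejects_nonpositive_denominator():
    with pytest.raises(ValidationError):
        compute_kri(10.0, 0.0)


# -- peak analysis ------------------------------------------------------------


def _toy_dataset(traces: dict, times=None) -> assays.TimeCourseDataset:
    times = np.arange(0.0, 10.0) if times is None else times
    frames = []
    for (cond, rep), vals in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_min": times,
                    "condition_id": cond,
                    "agonist": "A",
                    "agonist_conc_nM": 1.0,
                    "antagonist": "",
                    "antagonist_conc_nM": 0.0,
                    "replicate": rep,
                    "readout": "camp",
                    "value": vals,
                }
            )
        )
    return assays.TimeCourseDataset(data=pd.concat(frames, ignore_index=True), metadata={})


def test_peak_of_monotone_trace_is_last_sample_minus_baseline():
    t = np.arange(0.0, 10.0)
    ds = _toy_dataset({("c", 0): 2.0 * t + 5.0})
    peaks = peak_response(ds)
    assert peaks["peak"].iloc[0] == pytest.approx(2.0 * 9.0)


def test_peak_of_flat_trace_is_zero():
    ds = _toy_dataset({("c", 0): np.full(10, 7.0)})
    assert peak_response(ds)["peak"].iloc[0] == pytest.approx(0.0)


def test_peak_matches_noiseless_generator_maximum(sp_control_dataset, sp_control_peaks):
    """Generator oracle: with no noise the peak equals max(trace) - first sample."""
    top_cond = sp_control_peaks.sort_values("agonist_conc_nM").iloc[-1]
    trace = sp_control_dataset.data.query(
        "condition_id == @top_cond.condition_id and replicate == 0"
    ).sort_values("time_min")
    expected = trace["value"].max() - trace["value"].iloc[0]
    assert top_cond["peak"] == pytest.approx(expected)
    peak_t = trace.loc[trace["value"].idxmax(), "time_min"]
    assert 20.0 <= peak_t <= 30.0


# -- variable-slope fitting ---------------------------------------------------


def _hill(conc, ec50, hill=1.0, top=100.0, bottom=0.0):
    return bottom + (top - bottom) / (1.0 + (ec50 / np.asarray(conc)) ** hill)


def test_fit_recovers_generating_ec50_exactly():
    """Noiseless curve generated at EC50 = 2.2 nM is recovered to 1e-6 relative."""
    conc = np.logspace(-2, 2, 9) * 2.2
    fit = fit_concentration_response((conc, _hill(conc, 2.2)))
    assert fit.converged
    assert fit.ec50 == pytest.approx(2.2, rel=1e-6)
    assert fit.emax == pytest.approx(100.0, rel=1e-6)


def test_fit_recovers_unit_hill_slope():
    conc = np.logspace(-2, 2, 11) * 5.0
    fit = fit_concentration_response((conc, _hill(conc, 5.0, hill=1.0)))
    assert fit.hill == pytest.approx(1.0, abs=0.01)


def test_constant_response_flagged_not_raised():
    conc = np.logspace(-2, 2, 8)
    fit = fit_concentration_response((conc, np.full(8, 3.0)))
    assert not fit.converged
    assert np.isnan(fit.ec50)


def test_fit_requires_five_distinct_concentrations():
    with pytest.raises(ValidationError):
        ConcentrationResponseModel([1, 2, 3, 4], [0, 1, 2, 3])


def test_descending_fit_recovers_ic50():
    conc = np.logspace(-2, 2, 9) * 0.5
    resp = 100.0 - _hill(conc, 0.5)  # descending, IC50 = 0.5 nM
    fit = fit_inhibition((conc, resp))
    assert fit.converged
    assert fit.ic50 == pytest.approx(0.5, rel=1e-4)


def test_ic50_increases_with_agonist_challenge(sp, fast_antagonist):
    """Gaddum-limit behaviour: a stiffer agonist challenge needs more antagonist."""
    ic50s = []
    for challenge_mult in (2.0, 20.0):
        protocol = assays.build_ic50_protocol(
            fast_antagonist,
            tuple(np.logspace(-2.2, 2.2, 9) * fast_antagonist.kd),
            sp,
            agonist_ec80=challenge_mult * sp.kd,
        )
        ds = assays.generate_dataset(protocol)
        fit = fit_inhibition(peak_response(ds))
        assert fit.converged
        ic50s.append(fit.ic50)
    assert ic50s[1] > ic50s[0]


# -- normalization ------------------------------------------------------------


def test_control_normalizes_to_100(sp_control_peaks):
    normed, factor = normalize_to_control(sp_control_peaks)
    fit = fit_concentration_response(normed)
    assert fit.emax == pytest.approx(100.0, abs=1e-6)


def test_half_control_condition_reads_50(sp_control_peaks):
    halved = sp_control_peaks.copy()
    halved["antagonist_conc_nM"] = 1.0  # pretend it is a treated condition
    halved["peak"] *= 0.5
    both = pd.concat([sp_control_peaks, halved], ignore_index=True)
    normed, _ = normalize_to_control(both)
    treated = normed[normed["antagonist_conc_nM"] == 1.0]
    fit = fit_concentration_response(treated)
    assert fit.emax == pytest.approx(50.0, abs=1e-4)


def test_normalization_invariant_to_readout_units(sp_control_peaks):
    """Multiplying all raw values by 7 leaves percentages unchanged."""
    scaled = sp_control_peaks.copy()
    scaled["peak"] *= 7.0
    a, _ = normalize_to_control(sp_control_peaks)
    b, _ = normalize_to_control(scaled)
    assert np.allclose(a["peak"], b["peak"])


def test_normalization_requires_positive_control():
    peaks = pd.DataFrame(
        {"agonist_conc_nM": [1.0] * 3, "antagonist_conc_nM": [0.0] * 3,
         "peak": [0.0, -1.0, 0.0], "replicate": [0, 1, 2], "condition_id": ["c"] * 3}
    )
    with pytest.raises(ValidationError):
        normalize_to_control(peaks)


# -- EC80 ---------------------------------------------------------------------


def test_ec80_algebra(sp_control_fit):
    fit = sp_control_fit
    assert compute_ec80(fit) == pytest.approx(fit.ec50 * 4.0 ** (1.0 / fit.hill))
    conc = np.logspace(-2, 2, 9)
    f1 = fit_concentration_response((conc, _hill(conc, 1.0, hill=1.0)))
    assert compute_ec80(f1) == pytest.approx(4.0, rel=1e-5)
    f2 = fit_concentration_response((conc, _hill(conc, 1.0, hill=2.0)))
    assert compute_ec80(f2) == pytest.approx(2.0, rel=1e-4)


def test_response_at_ec80_is_80_percent_of_top(sp_control_fit):
    ec80 = compute_ec80(sp_control_fit)
    predicted = sp_control_fit.predict([ec80])[0]
    span = sp_control_fit.emax - sp_control_fit.baseline
    frac = (predicted - sp_control_fit.baseline) / span
    assert frac == pytest.approx(0.80, abs=1e-6)


# -- onset --------------------------------------------------------------------


def test_onset_of_exact_line():
    t = np.arange(0.0, 12.0)
    ds = _toy_dataset({("c", 0): 5.0 * t}, times=t)
    res = compute_onset(ds, "c")
    assert res.slope == pytest.approx(5.0)
    assert res.n_points == 8  # samples at t = 1..8


def test_onset_of_constant_trace_is_zero():
    t = np.arange(0.0, 12.0)
    ds = _toy_dataset({("c", 0): np.full_like(t, 4.0)}, times=t)
    assert compute_onset(ds, "c").slope == pytest.approx(0.0)


def test_onset_requires_enough_samples():
    t = np.array([0.0, 4.0, 10.0])
    ds = _toy_dataset({("c", 0): t.copy()}, times=t)
    with pytest.raises(ValidationError):
        compute_onset(ds, "c")


def test_onset_matches_independent_slope_oracle(sp, sp_control_fit):
    """Noiseless EC80 trace: onset equals the closed-form OLS slope
    sum((t - tbar)(v - vbar)) / sum((t - tbar)^2) computed by hand, and the
    secant slope over the window brackets it to within a few percent."""
    ec80 = compute_ec80(sp_control_fit)
    ds = assays.generate_dataset(assays.build_single_timecourse_protocol(sp, ec80))
    res = compute_onset(ds)
    trace = ds.data.query("replicate == 0").sort_values("time_min")
    win = trace[(trace["time_min"] > 0) & (trace["time_min"] <= 8)]
    t = win["time_min"].to_numpy()
    v = win["value"].to_numpy()
    oracle = np.sum((t - t.mean()) * (v - v.mean())) / np.sum((t - t.mean()) ** 2)
    assert res.slope == pytest.approx(oracle, rel=1e-9)
    secant = (v[-1] - trace["value"].iloc[0]) / t[-1]
    assert res.slope == pytest.approx(secant, rel=0.15)


# -- Dunnett ------------------------------------------------------------------


def test_dunnett_identical_groups_not_significant():
    vals = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0])
    groups = {"control": vals, "a": vals.copy(), "b": vals.copy()}
    res = dunnett_anova(groups, "control", seed=0)
    assert (res.table["p_adj"] > 0.9).all()


def test_dunnett_detects_large_shift():
    rng = np.random.default_rng(0)
    groups = {
        "control": rng.normal(0, 1, 6),
        "shifted": rng.normal(10, 1, 6),
        "null": rng.normal(0, 1, 6),
    }
    res = dunnett_anova(groups, "control", seed=1)
    assert res.p_adj("shifted") < 0.001
    assert res.p_adj("null") > 0.05


def test_dunnett_adjustment_inflates_pointwise_p():
    """Adjusted p exceeds the single-comparison two-sided p."""
    rng = np.random.default_rng(3)
    control = rng.normal(0, 1, 8)
    groups = {"control": control, "a": rng.normal(1.1, 1, 8), "b": rng.normal(0.2, 1, 8)}
    res = dunnett_anova(groups, "control", seed=0)
    for label in ("a", "b"):
        t = float(res.table.loc[res.table["label"] == label, "t"].iloc[0])
        single = 2 * sps.t.sf(abs(t), res.df_resid)
        assert res.p_adj(label) >= single


def test_dunnett_agrees_with_scipy_reference():
    """Independent oracle: scipy's Dunnett implementation on the same data."""
    rng = np.random.default_rng(7)
    control = rng.normal(0, 1, 6)
    a = rng.normal(1.0, 1, 6)
    b = rng.normal(-0.5, 1, 6)
    res = dunnett_anova({"control": control, "a": a, "b": b}, "control", seed=0)
    ref = sps.dunnett(a, b, control=control)
    assert res.p_adj("a") == pytest.approx(ref.pvalue[0], abs=0.01)
    assert res.p_adj("b") == pytest.approx(ref.pvalue[1], abs=0.01)


def test_dunnett_rejects_zero_variance():
    groups = {"control": [1.0, 1.0], "a": [2.0, 2.0]}
    with pytest.raises(ValidationError):
        dunnett_anova(groups, "control")


# -- surmountability ----------------------------------------------------------


def test_surmountability_rules(sp_control_fit):
    table = pd.DataFrame(
        {
            "label": ["ns_97", "sig_82", "sig_8"],
            "mean_diff": [-3.0, -18.0, -92.0],
            "t": [-0.5, -4.0, -20.0],
            "p_adj": [0.8, 0.004, 1e-9],
        }
    )
    dunnett = analysis.DunnettResult(
        table=table, f_stat=50.0, f_pvalue=1e-6, alpha=0.05, df_resid=8, n_comparisons=3
    )
    labels = classify_surmountability(
        sp_control_fit, {"ns_97": 97.0, "sig_82": 82.0, "sig_8": 7.8}, dunnett
    )
    assert labels == {
        "ns_97": "surmountable",
        "sig_82": "partially insurmountable",
        "sig_8": "insurmountable",
    }
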