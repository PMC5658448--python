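"""Shared fixtures: canonical ligands and cached noiseless simulations."""

import numpy as np
import pandas as pd
import pytest

from kinsig import (
    LigandKinetics,
    analysis,
    assays,
)
from kinsig import fixtures as fx
from kinsig.assays import _condition_rng
from kinsig.transduction import NoiseModel, apply_noise


@pytest.fixture(scope="session")
def sp():
    return fx.SP


@pytest.fixture(scope="session")
def nka():
    return fx.NKA


@pytest.fixture(scope="session")
def radioligand():
    return fx.RADIOLIGAND


@pytest.fixture(scope="session")
def slow_antagonist():
    """Slowly dissociating antagonist: koff 0.005 min^-1, KD 0.1 nM."""
    return LigandKinetics("slow_ant", kon=0.05, koff=0.005, role="antagonist")


@pytest.fixture(scope="session")
def fast_antagonist():
    """Fast-equilibrating antagonist: koff 1 min^-1, same KD 0.1 nM."""
    return LigandKinetics("fast_ant", kon=10.0, koff=1.0, role="antagonist")


@pytest.fixture(scope="session")
def sp_concs(sp):
    """8 agonist concentrations spanning 4 log units around the SP KD."""
    return tuple(np.logspace(-2.0, 2.0, 8) * sp.kd)


@pytest.fixture(scope="session")
def sp_control_dataset(sp, sp_concs):
    """Noiseless agonist-only concentration-response (cAMP-like)."""
    protocol = assays.build_concentration_response_protocol(sp, sp_concs)
    return assays.generate_dataset(protocol, seed=0)


@pytest.fixture(scope="session")
def sp_control_peaks(sp_control_dataset):
    return analysis.peak_response(sp_control_dataset)


@pytest.fixture(scope="session")
def sp_control_fit(sp_control_peaks):
    return analysis.fit_concentration_response(sp_control_peaks)


# -- shared heavy simulation fixtures (used by property and acceptance tests)

@pytest.fixture(scope="session")
def kri_vs_koff(radioligand):
    """KRI across competitor koff at fixed KD (= radioligand KD), each
    competitor dosed at the concentration achieving ~50% inhibition at the t2
    read - the assay's actual design rule, which for slowly associating
    competitors lies far above the equilibrium IC50."""
    import warnings

    from kinsig.kinetics import competition_ic50_at_time

    kd = radioligand.kd
    out = {}
    for koff in (1e-4, 1e-3, 0.01, radioligand.koff, 0.1, 1.0):
        comp = LigandKinetics("comp", kon=koff / kd, koff=koff)
        conc = competition_ic50_at_time(comp, radioligand, 2.5, 120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # slow competitors sit above the
            protocol = assays.build_dual_point_protocol(  # equilibrium window
                radioligand, comp, I=conc
            )
        out[koff] = analysis.kri_from_dataset(assays.generate_dataset(protocol)).kri
    return out


@pytest.fixture(scope="session")
def antagonist_panel_fits(sp, sp_concs, sp_control_fit, fast_antagonist, slow_antagonist):
    """Noiseless concentration-response fits after 30-min pre-incubation with
    0.7 nM of a fast (koff 1 min^-1) or slow (koff 0.005 min^-1) antagonist,
    both with KD 0.1 nM."""
    fits = {}
    for ant in (fast_antagonist, slow_antagonist):
        protocol = assays.build_concentration_response_protocol(
            sp, sp_concs, antagonist=ant, antagonist_conc=0.7
        )
        ds = assays.generate_dataset(protocol)
        fits[ant.name] = analysis.fit_concentration_response(analysis.peak_response(ds))
    return fits


@pytest.fixture(scope="session")
def onset_fold_reductions(sp, nka, slow_antagonist):
    """Onset fold-reduction under 0.7 nM slow antagonist, each agonist
    challenged at the EC80 implied by its published functional potency
    (EC50 2.2 nM for SP, 483 nM for NKA; EC80 = 4x EC50 at unit slope)."""
    folds = {}
    for agonist, ec80 in ((sp, 4 * 2.2), (nka, 4 * 483.0)):
        ctrl = assays.generate_dataset(
            assays.build_single_timecourse_protocol(agonist, ec80)
        )
        treated = assays.generate_dataset(
            assays.build_single_timecourse_protocol(
                agonist, ec80, antagonist=slow_antagonist, antagonist_conc=0.7
            )
        )
        folds[agonist.name] = (
            analysis.compute_onset(ctrl).slope / analysis.compute_onset(treated).slope
        )
    return folds


@pytest.fixture(scope="session")
def recovery_errors(sp, sp_concs, sp_control_fit, slow_antagonist, antagonist_panel_fits):
    """Full-pipeline recovery over 100 seeded noisy experiments (cv = 0.05,
    3 replicates): control pEC50 error, and normalized Emax error of a
    slow-antagonist-treated curve against the noiseless-pipeline truth."""
    noise = NoiseModel(cv=0.05)
    ctrl_protocol = assays.build_concentration_response_protocol(sp, sp_concs, noise=noise)
    ant_protocol = assays.build_concentration_response_protocol(
        sp, sp_concs, antagonist=slow_antagonist, antagonist_conc=0.7, noise=noise
    )
    traces = []
    for protocol, ant_conc in ((ctrl_protocol, 0.0), (ant_protocol, 0.7)):
        for c in protocol.conditions():
            _, v, _ = assays.simulate_condition(protocol, c["agonist_conc_nM"], ant_conc)
            traces.append((c["condition_id"], c["agonist_conc_nM"], ant_conc, v))

    truth_pec50 = sp_control_fit.pec50
    truth_emax_pct = (
        100.0 * antagonist_panel_fits[slow_antagonist.name].emax / sp_control_fit.emax
    )
    p_err, e_err = [], []
    for seed in range(100):
        rows = []
        for cid, conc, ant_conc, v in traces:
            key = f"{ant_conc:g}:{cid}"
            reps = apply_noise(v, NoiseModel(cv=0.05), 3, rng=_condition_rng(seed, key))
            for r in range(3):
                rows.append(
                    {
                        "condition_id": cid,
                        "agonist_conc_nM": conc,
                        "antagonist_conc_nM": ant_conc,
                        "replicate": r,
                        "peak": (reps[r] - reps[r][0]).max(),
                    }
                )
        peaks = pd.DataFrame(rows)
        ctrl_fit = analysis.fit_concentration_response(peaks[peaks["antagonist_conc_nM"] == 0])
        ant_fit = analysis.fit_concentration_response(peaks[peaks["antagonist_conc_nM"] > 0])
        p_err.append(abs(ctrl_fit.pec50 - truth_pec50))
        e_err.append(abs(100.0 * ant_fit.emax / ctrl_fit.emax - truth_emax_pct))
    return np.array(p_err), np.array(e_err)


@pytest.fixture(scope="session")
def dunnett_null_fwer():
    """Estimated family-wise error over 2000 all-null experiments (6 groups,
    3 replicates each, alpha 0.05)."""
    rng = np.random.default_rng(123)
    n_exp = 2000
    rejections = 0
    for _ in range(n_exp):
        groups = {f"g{j}": rng.normal(0.0, 1.0, 3) for j in range(5)}
        groups["control"] = rng.normal(0.0, 1.0, 3)
        res = analysis.dunnett_anova(groups, "control", seed=99)
        rejections += bool((res.table["p_adj"] < 0.05).any())
    return rejections / n_exp
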