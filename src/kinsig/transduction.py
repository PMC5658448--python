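"""Occupancy-to-readout transduction with desensitization and plate noise.

Real-time cAMP (luminescence) and impedance (cell morphology) readouts of GPCR
activation rise over tens of minutes and decay again even under sustained
agonist, peaking 20-30 min after stimulation.  The transient is produced here
by first-order desensitization of agonist-occupied receptor feeding an
operational-model-style hyperbolic amplifier:

    A(t) = max(b(t) - D(t), 0)          active (non-desensitized) occupancy
    dD/dt = k_des * A(t)                desensitized pool, D(0) = 0
    E(t) = gain * efficacy * A(t)       stimulus
    dr/dt = k_syn * E/(1 + E) - k_deg * (r - basal),   r(0) = basal

where b(t) is fractional agonist occupancy.  The hyperbolic coupling gives
receptor reserve (EC50 of the readout falls below the agonist KD as ``gain``
grows) and lets slowly dissociating antagonists depress the maximal response
rather than merely right-shifting it.

Two named calibrations are shipped: ``camp`` (lower gain, noisier, RLU-like)
and ``impedance`` (higher gain, hence left-shifted potencies, NCI-like).  Both
are calibrated so a saturating agonist peaks between 20 and 30 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import NumericalError, OccupancyTrajectory, ValidationError

__all__ = [
    "TransductionParams",
    "NoiseModel",
    "ResponseTrajectory",
    "CALIBRATIONS",
    "get_calibration",
    "simulate_readout",
    "apply_noise",
]


@dataclass(frozen=True)
class TransductionParams:
    """Parameters of the occupancy-to-response stage.

    efficacy : intrinsic efficacy of the agonist, in [0, 1].
    gain : transduction amplification (tau-like); > 0.
    k_syn : maximal response synthesis rate, readout units / min.
    k_deg : response decay rate, 1/min.
    k_des : desensitization rate of agonist-occupied receptor, 1/min.
    basal : baseline readout level.
    """

    efficacy: float = 1.0
    gain: float = 5.0
    k_syn: float = 100.0
    k_deg: float = 0.08
    k_des: float = 0.06
    basal: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValidationError(f"efficacy must be in [0, 1], got {self.efficacy}")
        if not self.gain > 0:
            raise ValidationError(f"gain must be positive, got {self.gain}")
        for attr in ("k_syn", "k_deg", "k_des"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be non-negative")

    @property
    def ceiling(self) -> float:
        """Upper bound on the response: basal + k_syn/k_deg."""
        return self.basal + self.k_syn / self.k_deg

    def replace(self, **kw) -> "TransductionParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative-plus-additive Gaussian plate noise.

    Each observed value is ``v * (1 + e_m) + e_a`` with ``e_m ~ N(0, cv)`` and
    ``e_a ~ N(0, additive_sd)``, drawn independently per well and time point.
    Luminescence and impedance scatter scales with signal, hence the
    multiplicative term; ``cv`` defaults mirror typical replicate scatter
    (5-15%).
    """

    cv: float = 0.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.additive_sd < 0:
            raise ValidationError("cv and additive_sd must be non-negative")

    def to_dict(self) -> dict:
        return {"cv": self.cv, "additive_sd": self.additive_sd, "seed": self.seed}


@dataclass(frozen=True)
class ResponseTrajectory:
    """A noiseless transduced readout on the occupancy time grid."""

    times: np.ndarray
    value: np.ndarray
    readout: str = "camp"

    def at(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.value)

    @property
    def peak_time(self) -> float:
        """Grid time of the maximal response."""
        return float(self.times[int(np.argmax(self.value))])


CALIBRATIONS: dict[str, TransductionParams] = {
    # RLU-like: modest amplification, so slow-antagonist blockade depresses Emax
    "camp": TransductionParams(
        efficacy=1.0, gain=5.0, k_syn=100.0, k_deg=0.08, k_des=0.06, basal=10.0
    ),
    # NCI-like: 10x higher amplification -> systematically left-shifted potencies
    # and weaker Emax depression (more receptor reserve)
    "impedance": TransductionParams(
        efficacy=1.0, gain=50.0, k_syn=2.0, k_deg=0.10, k_des=0.12, basal=0.2
    ),
}

DEFAULT_NOISE: dict[str, NoiseModel] = {
    "camp": NoiseModel(cv=0.10, additive_sd=0.0),
    "impedance": NoiseModel(cv=0.05, additive_sd=0.0),
}


def get_calibration(name: str) -> TransductionParams:
    try:
        return CALIBRATIONS[name]
    except KeyError:
        raise ValidationError(
            f"unknown calibration {name!r}; available: {sorted(CALIBRATIONS)}"
        ) from None


def simulate_readout(
    occupancy: OccupancyTrajectory,
    params: TransductionParams,
    agonist: str,
    readout: str = "camp",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ResponseTrajectory:
    """Transduce an agonist occupancy trajectory into a readout time course.

    ``agonist`` names the bound series in ``occupancy`` that drives the
    response; occupancy is interpolated linearly between grid points.  The
    result is returned on the occupancy grid.
    """
    b = occupancy.series(agonist) / occupancy.r_tot  # fractional occupancy
    times = occupancy.times

    def frac(t: float) -> float:
        return float(np.interp(t, times, b))

    ge = params.gain * params.efficacy

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        d, r = y
        a = max(frac(t) - d, 0.0)
        e = ge * a
        return np.array(
            [params.k_des * a, params.k_syn * e / (1.0 + e) - params.k_deg * (r - params.basal)]
        )

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        np.array([0.0, params.basal]),
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        max_step=1.0,  # occupancy is tabulated; keep steps below its resolution
    )
    if not sol.success:
        raise NumericalError(f"transduction integration failed: {sol.message}")
    return ResponseTrajectory(times=times.copy(), value=sol.y[1], readout=readout)


def apply_noise(
    values: np.ndarray,
    noise: NoiseModel,
    n_replicates: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Replicate a trace with multiplicative-plus-additive Gaussian noise.

    Returns an array of shape ``(n_replicates, len(values))``.  Reproducible:
    without an explicit ``rng``, the generator is seeded from ``noise.seed``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    values = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    shape = (n_replicates, values.size)
    mult = rng.normal(0.0, noise.cv, size=shape) if noise.cv else np.zeros(shape)
    add = rng.normal(0.0, noise.additive_sd, size=shape) if noise.additive_sd else np.zeros(shape)
    return values[None, :] * (1.0 + mult) + add
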