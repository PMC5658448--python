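"""Mass-action kinetics of competitive ligand binding to a single receptor pool.

The model is the standard pharmacological one: each ligand i binds a shared
receptor R with association rate ``kon_i`` (nM^-1 min^-1) and dissociates with
``koff_i`` (min^-1),

    dRL_i/dt = kon_i * L_i(t) * R(t) - koff_i * RL_i(t),
    R(t) = r_tot - sum_i RL_i(t),

with free ligand concentrations L_i(t) held piecewise-constant by an addition
schedule (no depletion; plate assays run at large volume excess).  Pre-incubation
with an antagonist is simply an earlier addition event.

Closed forms used as oracles and design helpers:

* :func:`motulsky_mahan_binding` -- the biexponential solution for a radioligand
  competing with one unlabelled ligand, both starting unbound (Motulsky & Mahan,
  Mol Pharmacol 1984).
* :func:`gaddum_occupancy` -- equilibrium occupancy under competitive inhibition.
* :func:`schild_shift` -- the surmountable-limit dose ratio 1 + [B]/KD_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "NumericalError",
    "LigandKinetics",
    "ReceptorSystem",
    "AdditionSchedule",
    "OccupancyTrajectory",
    "simulate_binding",
    "motulsky_mahan_binding",
    "gaddum_occupancy",
    "schild_shift",
    "competition_ic50",
    "competition_ic50_at_time",
]

ROLES = ("agonist", "antagonist", "radioligand")


class ConfigurationError(ValueError):
    """A protocol or system references unknown entities or inconsistent settings."""


class ValidationError(ValueError):
    """An input value violates a documented precondition."""


class NumericalError(RuntimeError):
    """The ODE integrator failed to meet its tolerance."""


@dataclass(frozen=True)
class LigandKinetics:
    """Kinetic identity of one ligand.

    Parameters
    ----------
    name : str
        Label used throughout schedules and datasets.
    kon : float
        Association rate constant, nM^-1 min^-1.
    koff : float
        Dissociation rate constant, min^-1.
    role : str
        One of ``agonist``, ``antagonist``, ``radioligand``.  Purely
        declarative; the binding ODE treats all ligands identically.
    """

    name: str
    kon: float
    koff: float
    role: str = "antagonist"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("ligand name must be non-empty")
        if not (self.kon > 0 and math.isfinite(self.kon)):
            raise ValidationError(f"kon must be positive and finite, got {self.kon}")
        if not (self.koff > 0 and math.isfinite(self.koff)):
            raise ValidationError(f"koff must be positive and finite, got {self.koff}")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant KD = koff/kon, nM."""
        return self.koff / self.kon

    @property
    def pkd(self) -> float:
        """Affinity as -log10(KD in molar); comparable to a pKi."""
        return -math.log10(self.kd * 1e-9)

    @property
    def residence_time(self) -> float:
        """Receptor residence time 1/koff, min."""
        return 1.0 / self.koff

    def with_role(self, role: str) -> "LigandKinetics":
        return LigandKinetics(self.name, self.kon, self.koff, role)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kon_per_nM_per_min": self.kon,
            "koff_per_min": self.koff,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LigandKinetics":
        return cls(
            name=d["name"],
            kon=d["kon_per_nM_per_min"],
            koff=d["koff_per_min"],
            role=d.get("role", "antagonist"),
        )


@dataclass(frozen=True)
class ReceptorSystem:
    """A receptor pool plus the ligands that may bind it.

    ``r_tot`` defaults to 1.0 so occupancies are fractional; receptor reserve is
    modelled downstream through transduction gain, not through receptor density.
    """

    ligands: tuple[LigandKinetics, ...]
    r_tot: float = 1.0

    def __init__(self, ligands: Iterable[LigandKinetics], r_tot: float = 1.0):
        ligands = tuple(ligands)
        names = [lig.name for lig in ligands]
        if len(set(names)) != len(names):
            raise ValidationError(f"ligand names must be unique, got {names}")
        if not (r_tot > 0 and math.isfinite(r_tot)):
            raise ValidationError(f"r_tot must be positive, got {r_tot}")
        object.__setattr__(self, "ligands", ligands)
        object.__setattr__(self, "r_tot", float(r_tot))

    def __getitem__(self, name: str) -> LigandKinetics:
        for lig in self.ligands:
            if lig.name == name:
                return lig
        raise ConfigurationError(f"unknown ligand {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lig.name for lig in self.ligands)


@dataclass(frozen=True)
class AdditionSchedule:
    """Piecewise-constant free-ligand concentrations.

    Each event ``(time, name, conc)`` sets ligand ``name``'s free concentration
    to ``conc`` nM from ``time`` onward.  Event times must be non-decreasing,
    non-negative and strictly below ``horizon``.
    """

    events: tuple[tuple[float, str, float], ...]
    horizon: float

    def __init__(self, events: Iterable[tuple[float, str, float]], horizon: float):
        events = tuple((float(t), str(n), float(c)) for t, n, c in events)
        if not (horizon > 0 and math.isfinite(horizon)):
            raise ValidationError(f"horizon must be positive, got {horizon}")
        times = [t for t, _, _ in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("event times must be non-decreasing")
        for t, name, c in events:
            if t < 0 or t >= horizon:
                raise ValidationError(f"event time {t} outside [0, horizon)")
            if c < 0:
                raise ValidationError(f"negative concentration {c} for {name!r}")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "horizon", float(horizon))

    @property
    def ligand_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, name, _ in self.events:
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    def breakpoints(self) -> np.ndarray:
        """Sorted unique event times plus 0 and the horizon."""
        ts = {0.0, self.horizon}
        ts.update(t for t, _, _ in self.events)
        return np.array(sorted(ts))

    def concentrations_at(self, t: float, names: Sequence[str]) -> np.ndarray:
        """Free concentrations of ``names`` on the segment starting at time t."""
        conc = {n: 0.0 for n in names}
        for et, name, c in self.events:
            if et <= t and name in conc:
                conc[name] = c
        return np.array([conc[n] for n in names])


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Receptor occupancy over time for every ligand in the system.

    Free receptor is defined as ``r_tot - sum(bound)``, so mass conservation is
    exact by construction; the integrator's accuracy shows up only in the
    individual bound series.
    """

    times: np.ndarray
    bound: dict[str, np.ndarray]
    r_tot: float

    @property
    def free_receptor(self) -> np.ndarray:
        total = np.zeros_like(self.times, dtype=float)
        for series in self.bound.values():
            total = total + series
        return self.r_tot - total

    def series(self, name: str) -> np.ndarray:
        try:
            return self.bound[name]
        except KeyError:
            raise ConfigurationError(f"no bound series for ligand {name!r}") from None

    def at(self, name: str, t: float | np.ndarray) -> np.ndarray:
        """Bound concentration of ``name`` at time(s) t, linear interpolation."""
        return np.interp(t, self.times, self.series(name))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time_min, species, value."""
        frames = [
            pd.DataFrame(
                {"time_min": self.times, "species": "free_receptor", "value": self.free_receptor}
            )
        ]
        for name, series in self.bound.items():
            frames.append(
                pd.DataFrame({"time_min": self.times, "species": name, "value": series})
            )
        return pd.concat(frames, ignore_index=True)


def simulate_binding(
    system: ReceptorSystem,
    schedule: AdditionSchedule,
    grid_step: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OccupancyTrajectory:
    """Integrate the competitive binding ODE under an addition schedule.

    Event times are hard breakpoints: the integration restarts at each one, so
    the piecewise-constant inputs never hide a discontinuity inside a step.  The
    returned grid is the union of a uniform ``grid_step`` grid and all event
    times.

    Raises
    ------
    ConfigurationError
        If the schedule references a ligand absent from the system.
    ValidationError
        If ``grid_step`` is not positive.
    NumericalError
        If the stiff integrator fails to meet tolerance on any segment.
    """
    if grid_step <= 0:
        raise ValidationError(f"grid_step must be positive, got {grid_step}")
    for name in schedule.ligand_names:
        system[name]  # raises ConfigurationError on unknown names

    names = list(system.names)
    kon = np.array([lig.kon for lig in system.ligands])
    koff = np.array([lig.koff for lig in system.ligands])
    r_tot = system.r_tot

    grid = np.union1d(
        np.arange(0.0, schedule.horizon + grid_step / 2, grid_step), schedule.breakpoints()
    )
    grid = grid[(grid >= 0.0) & (grid <= schedule.horizon)]

    x = np.zeros(len(names))
    out = np.zeros((len(grid), len(names)))
    out[0] = x
    bps = schedule.breakpoints()
    for t0, t1 in zip(bps[:-1], bps[1:]):
        conc = schedule.concentrations_at(t0, names)
        a = kon * conc

        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            free = r_tot - y.sum()
            return a * free - koff * y

        mask = (grid > t0) & (grid <= t1)
        seg_times = grid[mask]
        # grid contains every breakpoint, so seg_times always ends at t1
        t_eval = seg_times if seg_times.size and seg_times[-1] == t1 else np.append(seg_times, t1)
        sol = solve_ivp(rhs, (t0, t1), x, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalError(f"integrator failed on segment [{t0}, {t1}]: {sol.message}")
        if seg_times.size:
            out[mask] = sol.y[:, : seg_times.size].T
        x = sol.y[:, -1]

    bound = {name: np.clip(out[:, j], 0.0, None) for j, name in enumerate(names)}
    return OccupancyTrajectory(times=grid, bound=bound, r_tot=r_tot)


def motulsky_mahan_binding(
    radio: LigandKinetics,
    competitor: LigandKinetics,
    L: float,
    I: float,
    r_tot: float = 1.0,
    t: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Closed-form radioligand binding in the presence of one competitor.

    Both ligands are co-added at t = 0 to an unoccupied receptor pool; free
    concentrations are constant.  Returns the bound-radioligand concentration
    (same units as ``r_tot``) at time(s) ``t`` minutes.

    The solution is the textbook biexponential with observed rates

        KA = kon_r*L + koff_r,  KB = kon_c*I + koff_c,
        KF, KS = 0.5 * (KA + KB +/- sqrt((KA - KB)^2 + 4*kon_r*kon_c*L*I)).

    The degenerate repeated-root case KF == KS is evaluated by its analytic
    limit rather than the generic formula.
    """
    if L < 0 or I < 0:
        raise ValidationError("concentrations must be non-negative")
    t = np.asarray(t, dtype=float)
    k1, k2 = radio.kon, radio.koff
    k3, k4 = competitor.kon, competitor.koff
    ka = k1 * L + k2
    kb = k3 * I + k4
    disc = math.sqrt((ka - kb) ** 2 + 4.0 * k1 * k3 * L * I)
    kf = 0.5 * (ka + kb + disc)
    ks = 0.5 * (ka + kb - disc)
    amp = r_tot * k1 * L
    if disc <= 1e-10 * kf:
        # repeated root: B(t) = amp * [k4/K^2 (1 - e^-Kt) + t e^-Kt (1 - k4/K)]
        k = kf
        val = amp * (k4 / k**2 * (1.0 - np.exp(-k * t)) + t * np.exp(-k * t) * (1.0 - k4 / k))
    else:
        val = (
            amp
            / (kf - ks)
            * (
                k4 * (kf - ks) / (kf * ks)
                + (k4 - kf) / kf * np.exp(-kf * t)
                - (k4 - ks) / ks * np.exp(-ks * t)
            )
        )
    return val if val.ndim else float(val)


def gaddum_occupancy(
    agonist: LigandKinetics,
    L: float,
    competitors: Sequence[tuple[LigandKinetics, float]] = (),
) -> float:
    """Equilibrium fractional occupancy of ``agonist`` under competition.

    Gaddum's equation: (L/KD) / (1 + L/KD + sum_j I_j/KD_j), in [0, 1).
    """
    if L < 0:
        raise ValidationError("agonist concentration must be non-negative")
    num = L / agonist.kd
    denom = 1.0 + num
    for comp, conc in competitors:
        if conc < 0:
            raise ValidationError("competitor concentration must be non-negative")
        denom += conc / comp.kd
    return num / denom


def schild_shift(antagonist: LigandKinetics, I: float) -> float:
    """Equilibrium (surmountable-limit) dose ratio 1 + [B]/KD_B."""
    if I < 0:
        raise ValidationError("antagonist concentration must be non-negative")
    return 1.0 + I / antagonist.kd


def competition_ic50(competitor: LigandKinetics, radio: LigandKinetics, L: float) -> float:
    """Competitor concentration halving equilibrium radioligand binding.

    Cheng–Prusoff for a competitive system: IC50 = KD_c * (1 + L/KD_r).  Used
    to place dual-point competitors inside the 30-70% inhibition design window.
    """
    if L < 0:
        raise ValidationError("radioligand concentration must be non-negative")
    return competitor.kd * (1.0 + L / radio.kd)


def competition_ic50_at_time(
    competitor: LigandKinetics, radio: LigandKinetics, L: float, t: float
) -> float:
    """Competitor concentration halving radioligand binding at read time ``t``.

    Slowly associating competitors need far more than their equilibrium IC50 to
    reach 50% inhibition within a finite incubation; experimentally the
    dual-point concentration is titrated to the observed inhibition at the
    read, which this helper reproduces by inverting the closed-form solution.
    Falls back to the equilibrium IC50 when the two coincide.
    """
    from scipy.optimize import brentq

    if L < 0 or t <= 0:
        raise ValidationError("need L >= 0 and t > 0")
    target = 0.5 * motulsky_mahan_binding(radio, competitor, L, 0.0, 1.0, t)

    def deficit(I: float) -> float:
        return motulsky_mahan_binding(radio, competitor, L, I, 1.0, t) - target

    lo = competition_ic50(competitor, radio, L)
    if abs(deficit(lo)) < 1e-12 * target:
        return lo
    hi = lo
    while deficit(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise NumericalError("could not bracket the finite-time IC50")
    return float(brentq(deficit, lo * 1e-6, hi, xtol=1e-12, rtol=1e-12))
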