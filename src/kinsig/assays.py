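"""In-silico assay protocols and tidy time-course dataset generation.

Four experiment families are supported, mirroring how real-time plate assays
of antagonist kinetics are actually run:

* ``conc_response`` -- agonist titration, optionally after a fixed-concentration
  antagonist pre-incubation (default 30 min).
* ``ic50_at_ec80`` -- antagonist titration pre-incubated before a fixed EC80
  agonist challenge, plus an antagonist-free control.
* ``dual_point`` -- radioligand + competitor co-addition read at two times
  (default t1 = 30 min, t2 = 120 min), the input to the kinetic rate index.
* ``single_timecourse`` -- one condition, full trace.

Time origin convention: exported functional time courses start at agonist
addition (t = 0); the antagonist pre-incubation occupies internal negative
time and is shifted out before export.  Dual-point assays use co-addition at
t = 0.

Datasets are tidy tables (one row per well per time point) with a JSON-able
metadata block sufficient to regenerate them bit-exactly.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    AdditionSchedule,
    ConfigurationError,
    LigandKinetics,
    ReceptorSystem,
    ValidationError,
    competition_ic50,
    gaddum_occupancy,
    simulate_binding,
)
from .transduction import (
    NoiseModel,
    apply_noise,
    get_calibration,
    simulate_readout,
)

__all__ = [
    "AssayProtocol",
    "TimeCourseDataset",
    "build_concentration_response_protocol",
    "build_ic50_protocol",
    "build_dual_point_protocol",
    "build_single_timecourse_protocol",
    "generate_dataset",
]

GENERATOR_VERSION = "kinsig-0.1.0"

PROTOCOL_KINDS = ("conc_response", "ic50_at_ec80", "dual_point", "single_timecourse")


@dataclass(frozen=True)
class AssayProtocol:
    """A fully specified in-silico experiment.

    ``agonist_concs`` enumerates conditions for ``conc_response``;
    ``antagonist_concs`` enumerates conditions for ``ic50_at_ec80`` (agonist
    fixed at its EC80).  For ``dual_point`` the agonist slot holds the
    radioligand and ``read_times`` gives (t1, t2).
    """

    kind: str
    agonist: LigandKinetics
    agonist_concs: tuple[float, ...]
    antagonist: Optional[LigandKinetics] = None
    antagonist_concs: tuple[float, ...] = ()
    preincubation_min: float = 30.0
    read_horizon_min: float = 45.0
    read_times: Optional[tuple[float, float]] = None
    calibration: str = "camp"
    n_replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValidationError(f"kind must be one of {PROTOCOL_KINDS}, got {self.kind!r}")
        for seq, label in ((self.agonist_concs, "agonist"), (self.antagonist_concs, "antagonist")):
            arr = np.asarray(seq, dtype=float)
            if arr.size and (arr <= 0).any():
                raise ValidationError(f"{label} concentration series must be strictly positive")
            if arr.size > 1 and (np.diff(arr) <= 0).any():
                raise ValidationError(f"{label} concentration series must be strictly increasing")
        if self.antagonist is None and self.antagonist_concs:
            raise ValidationError("antagonist concentrations given without an antagonist")
        if self.kind == "dual_point":
            if self.read_times is None or len(self.read_times) != 2:
                raise ValidationError("dual_point requires exactly two read times")
            t1, t2 = self.read_times
            if not 0 < t1 < t2:
                raise ValidationError(f"dual_point needs 0 < t1 < t2, got {self.read_times}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.preincubation_min < 0:
            raise ValidationError("preincubation_min must be >= 0")

    # -- condition enumeration ------------------------------------------------

    def conditions(self) -> list[dict]:
        """One dict per simulated condition: concentrations plus a stable id."""
        conds: list[dict] = []
        if self.kind == "conc_response":
            anta = self.antagonist_concs[0] if self.antagonist_concs else 0.0
            for la in self.agonist_concs:
                conds.append(self._condition(la, anta))
        elif self.kind == "ic50_at_ec80":
            la = self.agonist_concs[0]
            conds.append(self._condition(la, 0.0))  # antagonist-free control
            for ia in self.antagonist_concs:
                conds.append(self._condition(la, ia))
        elif self.kind in ("dual_point", "single_timecourse"):
            la = self.agonist_concs[0]
            ia = self.antagonist_concs[0] if self.antagonist_concs else 0.0
            conds.append(self._condition(la, ia))
        return conds

    def _condition(self, agonist_conc: float, antagonist_conc: float) -> dict:
        cid = f"{self.agonist.name}_{agonist_conc:g}"
        if self.antagonist is not None:
            cid += f"__{self.antagonist.name}_{antagonist_conc:g}"
        return {
            "condition_id": cid,
            "agonist_conc_nM": float(agonist_conc),
            "antagonist_conc_nM": float(antagonist_conc),
        }

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "agonist": self.agonist.to_dict(),
            "agonist_concs": list(self.agonist_concs),
            "antagonist": self.antagonist.to_dict() if self.antagonist else None,
            "antagonist_concs": list(self.antagonist_concs),
            "preincubation_min": self.preincubation_min,
            "read_horizon_min": self.read_horizon_min,
            "read_times": list(self.read_times) if self.read_times else None,
            "calibration": self.calibration,
            "n_replicates": self.n_replicates,
            "noise": self.noise.to_dict(),
            "grid_step": self.grid_step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayProtocol":
        return cls(
            kind=d["kind"],
            agonist=LigandKinetics.from_dict(d["agonist"]),
            agonist_concs=tuple(d["agonist_concs"]),
            antagonist=LigandKinetics.from_dict(d["antagonist"]) if d.get("antagonist") else None,
            antagonist_concs=tuple(d.get("antagonist_concs", ())),
            preincubation_min=d.get("preincubation_min", 30.0),
            read_horizon_min=d.get("read_horizon_min", 45.0),
            read_times=tuple(d["read_times"]) if d.get("read_times") else None,
            calibration=d.get("calibration", "camp"),
            n_replicates=d.get("n_replicates", 3),
            noise=NoiseModel(**d.get("noise", {})),
            grid_step=d.get("grid_step", 1.0),
        )


@dataclass
class TimeCourseDataset:
    """Tidy per-well readout table plus regeneration metadata.

    Columns: time_min, condition_id, agonist, agonist_conc_nM, antagonist,
    antagonist_conc_nM, replicate, readout, value.
    """

    data: pd.DataFrame
    metadata: dict

    COLUMNS = (
        "time_min",
        "condition_id",
        "agonist",
        "agonist_conc_nM",
        "antagonist",
        "antagonist_conc_nM",
        "replicate",
        "readout",
        "value",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"dataset missing columns {sorted(missing)}")
        key = self.data[["condition_id", "replicate", "time_min"]]
        if key.duplicated().any():
            raise ValidationError("(condition_id, replicate, time_min) must be unique")

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV with a JSON metadata sidecar (<path>.meta.json)."""
        path = Path(path)
        self.data.to_csv(path, index=False, float_format="%.12g")
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(self.metadata, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourseDataset":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(data=data, metadata=metadata)

    def regenerate(self) -> "TimeCourseDataset":
        """Rebuild the dataset from its own metadata (bit-exact round trip)."""
        protocol = AssayProtocol.from_dict(self.metadata["protocol"])
        return generate_dataset(
            protocol, r_tot=self.metadata.get("r_tot", 1.0), seed=self.metadata.get("seed")
        )

    def condition_table(self) -> pd.DataFrame:
        cols = ["condition_id", "agonist", "agonist_conc_nM", "antagonist", "antagonist_conc_nM"]
        return self.data[cols].drop_duplicates().reset_index(drop=True)


# -- protocol builders --------------------------------------------------------


def build_concentration_response_protocol(
    agonist: LigandKinetics,
    concs: Sequence[float],
    antagonist: Optional[LigandKinetics] = None,
    antagonist_conc: float = 0.0,
    preincubation_min: float = 30.0,
    calibration: str = "camp",
    n_replicates: int = 3,
    noise: Optional[NoiseModel] = None,
    read_horizon_min: float = 45.0,
) -> AssayProtocol:
    """Agonist titration after optional antagonist pre-incubation.

    The antagonist (if any) is added 30 min (default) before the agonist, as in
    the canonical insurmountability design with a 0.07/0.21/0.7 nM antagonist
    panel.  Warns if the series covers fewer than 6 points or under 3 log
    units; a sparse series makes the variable-slope fit fragile.
    """
    concs = tuple(sorted(float(c) for c in concs))
    if antagonist is None and antagonist_conc > 0:
        raise ValidationError("antagonist_conc > 0 requires an antagonist")
    if len(concs) < 6 or (len(concs) > 1 and np.log10(concs[-1] / concs[0]) < 3):
        warnings.warn(
            "concentration series should span >= 3 log units with >= 6 points "
            "for a stable variable-slope fit",
            stacklevel=2,
        )
    return AssayProtocol(
        kind="conc_response",
        agonist=agonist,
        agonist_concs=concs,
        antagonist=antagonist,
        antagonist_concs=(float(antagonist_conc),) if antagonist is not None and antagonist_conc > 0 else (),
        preincubation_min=float(preincubation_min),
        read_horizon_min=float(read_horizon_min),
        calibration=calibration,
        n_replicates=n_replicates,
        noise=noise or NoiseModel(),
    )


def build_ic50_protocol(
    antagonist: LigandKinetics,
    concs: Sequence[float],
    agonist: LigandKinetics,
    agonist_ec80: float,
    preincubation_min: float = 30.0,
    calibration: str = "camp",
    n_replicates: int = 3,
    noise: Optional[NoiseModel] = None,
) -> AssayProtocol:
    """Antagonist titration against a fixed EC80 agonist challenge.

    One condition per antagonist concentration plus an antagonist-free control;
    zero entries in ``concs`` are deduplicated into the control.  The EC80
    should come from a prior fit of the agonist-only experiment, mirroring lab
    practice, not from generating parameters.
    """
    if agonist_ec80 <= 0:
        raise ValidationError("agonist_ec80 must be positive")
    concs = tuple(sorted({float(c) for c in concs if float(c) > 0}))
    if not concs:
        raise ValidationError("antagonist concentration series is empty")
    return AssayProtocol(
        kind="ic50_at_ec80",
        agonist=agonist,
        agonist_concs=(float(agonist_ec80),),
        antagonist=antagonist,
        antagonist_concs=concs,
        preincubation_min=float(preincubation_min),
        calibration=calibration,
        n_replicates=n_replicates,
        noise=noise or NoiseModel(),
    )


def build_dual_point_protocol(
    radio: LigandKinetics,
    competitor: LigandKinetics,
    L: float = 2.5,
    I: Optional[float] = None,
    read_times: tuple[float, float] = (30.0, 120.0),
    noise: Optional[NoiseModel] = None,
    n_replicates: int = 1,
) -> AssayProtocol:
    """Dual-point competition association assay (radioligand + competitor).

    Radioligand (default 2.5 nM) and competitor are co-added at t = 0; bound
    radioligand is read at t1 and t2 (default 30 and 120 min).  If ``I`` is
    omitted it is placed at the competitor's equilibrium IC50; a competitor
    concentration whose equilibrium inhibition falls outside the 30-70% design
    window triggers a warning, not an error.
    """
    if L <= 0:
        raise ValidationError("radioligand concentration must be positive")
    if I is None:
        I = competition_ic50(competitor, radio, L)
    if I < 0:
        raise ValidationError("competitor concentration must be non-negative")
    if I > 0:
        b0 = gaddum_occupancy(radio, L)
        bi = gaddum_occupancy(radio, L, [(competitor, I)])
        inhibition = 1.0 - bi / b0
        if not 0.30 <= inhibition <= 0.70:
            warnings.warn(
                f"competitor at {I:g} nM gives {inhibition:.0%} equilibrium inhibition, "
                "outside the 30-70% design window",
                stacklevel=2,
            )
    return AssayProtocol(
        kind="dual_point",
        agonist=radio.with_role("radioligand"),
        agonist_concs=(float(L),),
        antagonist=competitor,
        antagonist_concs=(float(I),) if I > 0 else (),
        preincubation_min=0.0,
        read_horizon_min=float(read_times[1]),
        read_times=(float(read_times[0]), float(read_times[1])),
        calibration="camp",
        n_replicates=n_replicates,
        noise=noise or NoiseModel(),
    )


def build_single_timecourse_protocol(
    agonist: LigandKinetics,
    agonist_conc: float,
    antagonist: Optional[LigandKinetics] = None,
    antagonist_conc: float = 0.0,
    preincubation_min: float = 30.0,
    calibration: str = "camp",
    n_replicates: int = 3,
    noise: Optional[NoiseModel] = None,
    read_horizon_min: float = 45.0,
) -> AssayProtocol:
    """One condition, full functional trace (e.g. for onset analysis)."""
    return AssayProtocol(
        kind="single_timecourse",
        agonist=agonist,
        agonist_concs=(float(agonist_conc),),
        antagonist=antagonist,
        antagonist_concs=(float(antagonist_conc),) if antagonist is not None and antagonist_conc > 0 else (),
        preincubation_min=float(preincubation_min),
        read_horizon_min=float(read_horizon_min),
        calibration=calibration,
        n_replicates=n_replicates,
        noise=noise or NoiseModel(),
    )


# -- generation ---------------------------------------------------------------


def _condition_rng(seed: Optional[int], condition_id: str) -> np.random.Generator:
    """Per-condition substream, stable under condition reordering."""
    key = zlib.crc32(condition_id.encode())
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, key]))


def simulate_condition(
    protocol: AssayProtocol,
    agonist_conc: float,
    antagonist_conc: float,
    r_tot: float = 1.0,
):
    """Noiseless (times, values) for one condition in the export time frame."""
    ligands = [protocol.agonist]
    if protocol.antagonist is not None:
        ligands.append(protocol.antagonist)
    system = ReceptorSystem(ligands, r_tot=r_tot)

    if protocol.kind == "dual_point":
        events = [(0.0, protocol.agonist.name, agonist_conc)]
        if protocol.antagonist is not None and antagonist_conc > 0:
            events.append((0.0, protocol.antagonist.name, antagonist_conc))
        horizon = protocol.read_horizon_min
        schedule = AdditionSchedule(sorted(events), horizon)
        traj = simulate_binding(system, schedule, grid_step=protocol.grid_step)
        t1, t2 = protocol.read_times
        times = np.array([t1, t2])
        values = traj.at(protocol.agonist.name, times)
        return times, values, "binding"

    pre = protocol.preincubation_min
    events = []
    if protocol.antagonist is not None and antagonist_conc > 0:
        events.append((0.0, protocol.antagonist.name, antagonist_conc))
    events.append((pre, protocol.agonist.name, agonist_conc))
    horizon = pre + protocol.read_horizon_min
    schedule = AdditionSchedule(sorted(events), horizon)
    traj = simulate_binding(system, schedule, grid_step=protocol.grid_step)
    params = get_calibration(protocol.calibration)
    response = simulate_readout(traj, params, protocol.agonist.name, readout=protocol.calibration)
    # export frame: t = 0 at agonist addition
    mask = traj.times >= pre - 1e-9
    times = np.round(traj.times[mask] - pre, 9)
    values = response.value[mask]
    return times, values, protocol.calibration


def generate_dataset(
    protocol: AssayProtocol, r_tot: float = 1.0, seed: Optional[int] = None
) -> TimeCourseDataset:
    """Run binding -> transduction -> noise for every condition and replicate.

    Deterministic given ``seed``; each condition draws noise from its own
    substream keyed by the condition id, so adding or reordering conditions
    does not perturb the others.
    """
    frames = []
    for cond in protocol.conditions():
        times, values, readout = simulate_condition(
            protocol, cond["agonist_conc_nM"], cond["antagonist_conc_nM"], r_tot=r_tot
        )
        rng = _condition_rng(seed, cond["condition_id"])
        reps = apply_noise(values, protocol.noise, protocol.n_replicates, rng=rng)
        for rep in range(protocol.n_replicates):
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": times,
                        "condition_id": cond["condition_id"],
                        "agonist": protocol.agonist.name,
                        "agonist_conc_nM": cond["agonist_conc_nM"],
                        "antagonist": protocol.antagonist.name if protocol.antagonist else "",
                        "antagonist_conc_nM": cond["antagonist_conc_nM"],
                        "replicate": rep,
                        "readout": readout,
                        "value": reps[rep],
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    metadata = {
        "protocol": protocol.to_dict(),
        "r_tot": r_tot,
        "seed": seed,
        "generator_version": GENERATOR_VERSION,
    }
    return TimeCourseDataset(data=data, metadata=metadata)
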