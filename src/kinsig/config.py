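"""Schema-validated run configuration (YAML or JSON).

A run config names the ligand kinetic parameter sets, one protocol block, the
noise model, the analysis options and the global seed.  Validation is strict:
unknown keys are rejected (so a typo like ``kon_per_min`` fails loudly) and
every problem in the file is reported at once.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from .kinetics import ConfigurationError, LigandKinetics
from .transduction import NoiseModel

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LigandBlock(_Strict):
    name: str
    kon_per_nM_per_min: float = Field(gt=0)
    koff_per_min: float = Field(gt=0)
    role: Literal["agonist", "antagonist", "radioligand"] = "antagonist"

    def to_ligand(self) -> LigandKinetics:
        return LigandKinetics(self.name, self.kon_per_nM_per_min, self.koff_per_min, self.role)


class NoiseBlock(_Strict):
    cv: float = Field(default=0.0, ge=0)
    additive_sd: float = Field(default=0.0, ge=0)

    def to_noise(self, seed: int = 0) -> NoiseModel:
        return NoiseModel(cv=self.cv, additive_sd=self.additive_sd, seed=seed)


class ProtocolBlock(_Strict):
    kind: Literal["conc_response", "ic50_at_ec80", "dual_point", "single_timecourse"]
    agonist: str
    agonist_concs_nM: list[float] = Field(default_factory=list)
    antagonist: Optional[str] = None
    antagonist_concs_nM: list[float] = Field(default_factory=list)
    preincubation_min: float = Field(default=30.0, ge=0)
    read_horizon_min: float = Field(default=45.0, gt=0)
    t1_min: float = Field(default=30.0, gt=0)
    t2_min: float = Field(default=120.0, gt=0)
    radioligand_conc_nM: float = Field(default=2.5, gt=0)
    calibration: Literal["camp", "impedance"] = "camp"
    n_replicates: int = Field(default=3, ge=1)


class AnalysisBlock(_Strict):
    window_min: float = Field(default=8.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    normalize: bool = True


class RunConfig(_Strict):
    ligands: list[LigandBlock]
    protocol: ProtocolBlock
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    seed: int = 0
    r_tot: float = Field(default=1.0, gt=0)
    output_dir: str = "kinsig_out"

    def ligand(self, name: Optional[str]) -> Optional[LigandKinetics]:
        if name is None:
            return None
        for block in self.ligands:
            if block.name == name:
                return block.to_ligand()
        raise ConfigurationError(f"protocol references unknown ligand {name!r}")

    def to_protocol(self):
        """Build the AssayProtocol this config describes."""
        from . import assays

        p = self.protocol
        noise = self.noise.to_noise(seed=self.seed)
        agonist = self.ligand(p.agonist)
        antagonist = self.ligand(p.antagonist)
        if p.kind == "conc_response":
            return assays.build_concentration_response_protocol(
                agonist,
                p.agonist_concs_nM,
                antagonist=antagonist,
                antagonist_conc=p.antagonist_concs_nM[0] if p.antagonist_concs_nM else 0.0,
                preincubation_min=p.preincubation_min,
                calibration=p.calibration,
                n_replicates=p.n_replicates,
                noise=noise,
                read_horizon_min=p.read_horizon_min,
            )
        if p.kind == "ic50_at_ec80":
            return assays.build_ic50_protocol(
                antagonist,
                p.antagonist_concs_nM,
                agonist,
                agonist_ec80=p.agonist_concs_nM[0],
                preincubation_min=p.preincubation_min,
                calibration=p.calibration,
                n_replicates=p.n_replicates,
                noise=noise,
            )
        if p.kind == "dual_point":
            return assays.build_dual_point_protocol(
                agonist,
                antagonist,
                L=p.radioligand_conc_nM,
                I=p.antagonist_concs_nM[0] if p.antagonist_concs_nM else None,
                read_times=(p.t1_min, p.t2_min),
                noise=noise,
                n_replicates=p.n_replicates,
            )
        return assays.build_single_timecourse_protocol(
            agonist,
            p.agonist_concs_nM[0],
            antagonist=antagonist,
            antagonist_conc=p.antagonist_concs_nM[0] if p.antagonist_concs_nM else 0.0,
            preincubation_min=p.preincubation_min,
            calibration=p.calibration,
            n_replicates=p.n_replicates,
            noise=noise,
            read_horizon_min=p.read_horizon_min,
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run config.

    All schema violations are collected into one ConfigurationError naming the
    offending keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigurationError(f"invalid config {path}: {problems}") from None


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out (YAML by extension, else JSON)."""
    path = Path(path)
    payload = config.model_dump()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
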