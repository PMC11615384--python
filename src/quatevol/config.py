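"""Run configuration: schema, defaults, validation.

A single YAML (or JSON) file drives the pipeline.  Validation is strict —
unknown keys are rejected and all violations are reported together — because
silent config typos are the classic way reproducibility dies.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    pass


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: bool = True
    asr: bool = True
    traits: bool = True
    massphot: bool = True
    assays: bool = True


class TreeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    newick_path: str | None = None
    n_leaves: int = Field(12, ge=2)
    mean_branch_length: float = Field(0.3, gt=0)


class IndelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean_block_length: int = Field(10, ge=1)
    loss_rate: float = Field(0.05, ge=0)
    gain_rate: float = Field(0.01, ge=0)


class AlignmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fasta_path: str | None = None
    length: int = Field(300, ge=1)
    gamma_alpha: float = Field(1.0, gt=0)
    gamma_k: int = Field(4, ge=1)
    frequencies: str = "model"  # "model" or "empirical"
    indel: IndelConfig = IndelConfig()

    @model_validator(mode="after")
    def _check_freqs(self):
        if self.frequencies not in ("model", "empirical"):
            raise ValueError("frequencies must be 'model' or 'empirical'")
        return self


class AsrConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    altall_threshold: float = Field(0.2, gt=0, le=0.5)


class TraitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    traits_path: str | None = None
    alphabet: list[str] = ["dimer", "hexamer", "octamer", "polydisperse"]
    rate: float = Field(0.3, ge=0)


class ProteinSpec(BaseModel):
    """One synthetic protein: its assembly mixture and functional truth."""

    model_config = ConfigDict(extra="forbid")
    name: str
    composition: dict[int, float]
    monomer_kda: float = Field(48.0, gt=0)
    kcat_s: float = Field(50.0, gt=0)
    km_uM: float = Field(40.0, gt=0)
    melt_midpoints_C: list[float] = [70.0]
    growth_rate_h: float = Field(0.8, ge=0)

    @model_validator(mode="after")
    def _check_composition(self):
        tot = sum(self.composition.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"composition of {self.name!r} sums to {tot}, not 1")
        if any(n < 1 for n in self.composition):
            raise ValueError("stoichiometries must be >= 1")
        return self


class MassPhotConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_events: int = Field(5000, ge=100)
    sigma_rel: float = Field(0.04, ge=0)
    n_max: int = Field(12, ge=1)
    mass_floor_kda: float = Field(40.0, ge=0)
    mass_tol: float = Field(0.10, gt=0, le=0.5)
    theta_mono: float = Field(0.80, gt=0.5, le=1.0)
    theta_min: float = Field(0.05, gt=0, le=0.5)


class AssayConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epsilon_M_cm: float = Field(14150.0, gt=0)
    path_cm: float = Field(1.0, gt=0)
    split_C: float = 65.0
    enzyme_uM: float = Field(0.025, gt=0)
    substrate_uM: list[float] = [25, 50, 75, 100, 150, 250, 500]
    rate_noise_cv: float = Field(0.02, ge=0)
    replicates: int = Field(3, ge=1)
    melt_noise_sd: float = Field(0.02, ge=0)
    growth_noise_cv: float = Field(0.03, ge=0)


_DEFAULT_PROTEINS = [
    ProteinSpec(name="hexamer", composition={6: 1.0}, melt_midpoints_C=[77.6]),
    ProteinSpec(name="dimer", composition={2: 1.0}, kcat_s=60.0,
                melt_midpoints_C=[81.3]),
    ProteinSpec(name="polydisperse_ladder",
                composition={2: 0.42, 3: 0.05, 4: 0.22, 5: 0.03, 6: 0.15,
                             8: 0.08, 10: 0.05},
                kcat_s=45.0, melt_midpoints_C=[49.0, 67.5]),
]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stages: StageToggles = StageToggles()
    tree: TreeConfig = TreeConfig()
    alignment: AlignmentConfig = AlignmentConfig()
    asr: AsrConfig = AsrConfig()
    traits: TraitConfig = TraitConfig()
    massphot: MassPhotConfig = MassPhotConfig()
    assays: AssayConfig = AssayConfig()
    proteins: list[ProteinSpec] = Field(default_factory=lambda: list(_DEFAULT_PROTEINS))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(source) -> RunConfig:
    """Load and validate a config file (YAML or JSON) or a plain dict.

    All schema violations are collected into one error message; referenced
    files must exist.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raw = dict(source)
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise ConfigError("invalid configuration:\n" + "\n".join(lines)) from exc
    for label, p in (("tree.newick_path", cfg.tree.newick_path),
                     ("alignment.fasta_path", cfg.alignment.fasta_path),
                     ("traits.traits_path", cfg.traits.traits_path)):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{label} points to a missing file: {p}")
    return cfg
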