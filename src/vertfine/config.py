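"""Run configuration: a strict, flat YAML schema.

Every stochastic stage draws from the single run seed; unknown keys are
rejected so that a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .designs import FixtureParams
from .qc import QCThresholds

__all__ = ["RunConfig", "QCSettings", "SimSettings"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QCSettings(_Strict):
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.10
    hwe_p_min: float = 1e-6
    animal_call_rate_min: float = 0.95
    mendel_error_rate_max: float = 0.1

    def to_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.model_dump())


class SimSettings(_Strict):
    """Scale and effect knobs of the synthetic study."""

    chip_per_chrom: int = 600
    we_n_f2: int = 900
    su_n_offspring: int = 400
    et_n_f2: int = 61
    dll_n: int = 400
    trait_a: float = 0.5
    trait_sigma_e: float = 0.45
    trait_h2_poly: float = 0.1
    missing_rate: float = 0.0
    error_rate: float = 0.0

    def to_fixture_params(self) -> FixtureParams:
        return FixtureParams(
            chip_per_chrom=self.chip_per_chrom,
            we_n_f2=self.we_n_f2,
            su_n_offspring=self.su_n_offspring,
            et_n_f2=self.et_n_f2,
            dll_n=self.dll_n,
            trait_a=self.trait_a,
            trait_sigma_e=self.trait_sigma_e,
            trait_h2_poly=self.trait_h2_poly,
        )


class RunConfig(_Strict):
    seed: int = 1
    out_dir: str = "runs/demo"
    qc: QCSettings = Field(default_factory=QCSettings)
    sim: SimSettings = Field(default_factory=SimSettings)
    gwas_alpha: float = 0.05
    lod_drop: float = 2.0
    substitution_effect: float = 0.5  # prior QTL effect used by the Z test (vertebrae)
    min_progeny_group: int = 20  # smallest haplotype group a progeny test may use
    z_upper: float = 2.0
    z_lower: float = -2.0
    founder_alpha: float = 0.01
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def digest(self) -> str:
        """Hash of the scientific parameters (where outputs land and how
        verbosely we log do not affect the results)."""
        params = self.model_dump(exclude={"out_dir", "log_level"})
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
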