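"""Validated pipeline configuration (YAML-backed).

Unknown keys are rejected; every screening threshold carries its production
default (identity 0.9, contact-variance 3, binding energy 17 kcal/mol,
top-k 20, 220 nm band, learning rate 0.02, 30%/45% dropout, 2x256 LSTM).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CorpusStage(_Strict):
    input_fasta: str | None = None
    synth_n: int = 80
    synth_motif: str | None = "KRLWK"
    min_len: int = 9
    max_len: int = 15
    identity_threshold: float = Field(0.9, gt=0, le=1)


class ModelStage(_Strict):
    layers: int = 2
    units: int = 256
    dropout: list[float] = [0.30, 0.45]
    learning_rate: float = 0.02
    forget_gate_bias: float = 1.0
    epochs: int = 200


class SamplingStage(_Strict):
    n_draws: int = 1018
    temperature: float = 1.0
    max_len: int = 15


class CompareStage(_Strict):
    n_random: int = 200
    n_helical: int = 200


class CDStage(_Strict):
    enabled: bool = True
    lambda_nm: float = 220.0
    invert: bool = False
    reference_helix_fraction: float = 0.5


class ScreeningStage(_Strict):
    enabled: bool = True
    contacts_csv: str | None = None
    energies_csv: str | None = None
    n_total: int = 127
    n_low_variance: int = 57
    variance_cutoff: float = 3.0
    energy_cutoff_kcal: float = 17.0
    top_k: int = 20
    cpp: str = "RQIKIWFQNRRMKWKK"


class PipelineConfig(_Strict):
    format_version: int = 1
    seed: int = 0
    out_dir: str = "pepgen_run"
    corpus: CorpusStage = Field(default_factory=CorpusStage)
    model: ModelStage = Field(default_factory=ModelStage)
    sampling: SamplingStage = Field(default_factory=SamplingStage)
    compare: CompareStage = Field(default_factory=CompareStage)
    cd: CDStage = Field(default_factory=CDStage)
    screening: ScreeningStage = Field(default_factory=ScreeningStage)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; defaults are filled in."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
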