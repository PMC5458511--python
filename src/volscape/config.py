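"""Run configuration: one YAML file drives the whole pipeline.

Unknown keys are rejected so typos fail loudly; CLI flags override file
values. All randomness in a run flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "AlignParams", "PCAParams", "LandscapeParams", "ClassifierParams"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AlignParams(_Strict):
    angular_range: float = 6.0
    angular_step: float = 2.0
    shift_range: float = 8.0


class PCAParams(_Strict):
    n_components: int = 2
    count_weighted: bool = False


class LandscapeParams(_Strict):
    components: tuple[int, int] = (0, 1)
    bins: int = 32
    smoothing_sigma: float = 1.0
    cap_empty: bool = False


class ClassifierParams(_Strict):
    orientation_step: float = 10.0
    inplane_step: float = 5.0
    shift_range: int = 3
    shift_step: int = 3
    n_iterations: int = 3
    lowpass: float = 20.0
    ref_damping: float = 0.5


class RunConfig(_Strict):
    manifest: str
    reference: str
    cp_mask: str
    pca_mask: str
    outdir: str = "volscape_out"
    seed: int = 0
    align: AlignParams = AlignParams()
    pca: PCAParams = PCAParams()
    landscape: LandscapeParams = LandscapeParams()
    classifier: ClassifierParams = ClassifierParams()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (stamps all outputs)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
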