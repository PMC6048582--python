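"""Declarative run configuration, schema-validated.

One document holds every parameter that affects numerics, so a run is
reproducible from its config alone. Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["RunConfig", "load_montage_pairs", "MONTAGE_FILE"]

MONTAGE_FILE = Path(__file__).parent / "data" / "montage_emotiv_1020.yaml"


class RunConfig(BaseModel):
    """All module parameters in one validated document."""

    model_config = ConfigDict(extra="forbid")

    # wavelet
    f_b: float = 2.0
    f_c: float = 1.0
    # scale grid
    f_min: float = 100.0
    f_max: float = 600.0
    n_scales: int = 40
    # sum-rule matching
    tolerance: float = 0.05
    # sliding window
    T: float = 0.5
    dT1: float = 0.25
    # peaks / contours
    min_height: float = 0.1
    min_separation: float = 0.0
    contour_level: float = 0.5
    gp_source: str = "wbs"
    # pain features
    referencing: str = "NoR"  # NoR | RS
    asymmetry: str = "none"  # none | DAs | RAs
    band: str = "beta"
    n_sigma_R: float = 1.0
    n_sigma_P: float = 10.0
    k_persist: int = 3
    # misc
    exclude_coi: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not 0 < self.dT1 <= self.T:
            raise ValueError("need 0 < dT1 <= T")
        if self.referencing not in ("NoR", "RS"):
            raise ValueError("referencing must be NoR or RS")
        if self.asymmetry not in ("none", "DAs", "RAs"):
            raise ValueError("asymmetry must be none, DAs or RAs")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_dict(self) -> dict:
        return self.model_dump()


def load_montage_pairs(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Symmetric (left, right) channel pairs of the shipped 10/20 montage."""
    doc = yaml.safe_load(Path(path or MONTAGE_FILE).read_text())
    return [tuple(p) for p in doc["symmetric_pairs"]]
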