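"""Run configuration: one serializable record of every tunable threshold.

Configuration is plain TOML; every analysis output embeds the resolved
configuration and its hash, so reruns are attributable and byte-for-byte
reproducible on the same platform.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .bdna import HelixParams
from .interfaces import ClashCriterion

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of the pipelines, with package defaults."""

    twist: float = 36.0                 # deg per bp step
    rise: float = 3.38                  # angstrom per bp step
    overlap_cutoff: float = 0.6         # clash = vdW overlap >= this (A)
    sasa_probe: float = 1.4             # solvent probe radius (A)
    sasa_n_points: int = 960            # quadrature points per atom
    coorient_tol_deg: float = 18.0      # half a bp twist
    n_anchor_bp: int = 4                # bp used to frame-match docking
    max_clashes_pass: int = 0           # "clash-free" threshold
    lmin: int = 20                      # scan range, bp
    lmax: int = 45
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def helix_params(self) -> HelixParams:
        return HelixParams(twist=self.twist, rise=self.rise)

    def clash_criterion(self) -> ClashCriterion:
        return ClashCriterion(overlap_cutoff=self.overlap_cutoff)

    def as_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
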