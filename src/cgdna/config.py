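"""Structured run configuration (YAML) with validation and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .parameters import ElectrostaticsContext


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-identically.

    ``salt_mm`` maps to the published Debye lengths (100 mM -> 10 A,
    120 mM -> 8.8 A) unless an explicit ``kappa`` is given.
    """

    variant: str = "two_bead"               # two_bead | three_bead
    sequence: str | None = None             # DNA literal or FASTA path
    duplex: bool = True
    protein: str | None = None              # optional protein literal/FASTA
    salt_mm: float | None = 100.0
    kappa: float | None = None              # overrides salt_mm if set
    temperature: float | None = 300.0       # single-T runs
    ladder: list = field(default_factory=list)   # REMD temperatures
    swap_interval: int = 100
    dt_fs: float = 10.0
    tau_ps: float = 10.0
    n_steps: int = 100000
    n_equil: int = 0
    stride: int = 1000
    seed: int = 1
    box: float = 300.0
    hps_scale: str = "urry"
    umbrella_centers: list = field(default_factory=list)
    umbrella_k: float = 0.5975
    output: str = "cgdna_out"

    REQUIRED = ("variant", "sequence", "n_steps", "seed")

    def electrostatics(self) -> ElectrostaticsContext:
        if self.kappa is not None:
            return ElectrostaticsContext(kappa=float(self.kappa))
        return ElectrostaticsContext.from_salt(float(self.salt_mm))

    def validate(self) -> "RunConfig":
        missing = [k for k in self.REQUIRED if getattr(self, k) in (None, "")]
        if missing:
            raise ValueError("missing required config fields: "
                             + ", ".join(missing))
        if self.variant not in ("two_bead", "three_bead"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.salt_mm is None and self.kappa is None:
            raise ValueError("either salt_mm or kappa must be set")
        return self

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable hash of the semantic content (key order independent)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
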