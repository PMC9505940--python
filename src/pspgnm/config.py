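"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .gnm_core import ZERO_TOLERANCE
from .potentials import CONVENTIONS


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters.

    rc: contact cutoff between CA atoms, Angstrom (default 9).
    n_modes: slowest non-zero modes used for the pseudo-inverse (default 10;
        20 is the documented alternate).
    break_fraction: fraction of initial contacts broken during partial
        unfolding (default 0.5).
    convention: non-bonded spring sign convention (see pspgnm.potentials).
    scale: (slope, intercept) applied to the raw free-energy change; defaults
        to the identity so raw values are reported unless a benchmark-derived
        regression is supplied.
    entropy_from: which MSF enters the entropy term — "at_break" (MSF at the
        iteration the contact broke) or "native" (intact-structure MSF).
    zeros: whether evaluation includes defaulted-zero predictions.
    """

    rc: float = 9.0
    n_modes: int = 10
    break_fraction: float = 0.5
    convention: str = "boltzmann_negated"
    scale: tuple[float, float] = (1.0, 0.0)
    zero_tolerance: float = ZERO_TOLERANCE
    zeros: str = "include"
    entropy_from: str = "at_break"
    breaks_per_iter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise ValueError("rc must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if not 0 < self.break_fraction <= 1:
            raise ValueError("break_fraction must be in (0, 1]")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.zeros not in ("include", "exclude"):
            raise ValueError("zeros must be 'include' or 'exclude'")
        if self.entropy_from not in ("at_break", "native"):
            raise ValueError("entropy_from must be 'at_break' or 'native'")
        object.__setattr__(self, "scale", tuple(float(s) for s in self.scale))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale"] = list(self.scale)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "scale" in data:
            data["scale"] = tuple(data["scale"])
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
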