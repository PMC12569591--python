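"""Call-level domain types shared across the copy-number modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import math


@dataclass
class GeneCall:
    """Per-gene copy-number summary with significance annotation.

    ``state`` is -1 (loss), 0 (neutral / zeroed) or +1 (gain).
    """

    gene: str
    log2cnr: float
    z: float
    p: float
    q: float
    state: int
    chrom: str = ""
    start: int = 0
    end: int = 0
    n_amplicons: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isnan(self.q) and not math.isnan(self.p) and self.q < self.p - 1e-12:
            raise ValueError(f"gene {self.gene}: q ({self.q}) < p ({self.p})")
        if self.state not in (-1, 0, 1):
            raise ValueError(f"gene {self.gene}: state must be -1/0/+1")


@dataclass
class Segment:
    """One constant-copy-number segment with its significance annotation."""

    chrom: str
    start: int
    end: int
    n_markers: int
    mean_log2cnr: float
    z: float = float("nan")
    q: float = float("nan")
    state: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("segment must contain at least one marker")
        if self.end <= self.start:
            raise ValueError(f"segment [{self.start}, {self.end}) is empty")
        if self.state not in (-1, 0, 1):
            raise ValueError("segment state must be -1/0/+1")


@dataclass
class ArmCall:
    """Arm-level aneuploidy verdict for one sample."""

    arm: str
    direction: str  # "gain" | "loss" | "none"
    rc: float
    c: float
    direction_fraction: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not (0.0 <= self.rc <= 1.0 + 1e-12):
            raise ValueError(f"R_c out of [0, 1]: {self.rc}")

    @property
    def state(self) -> int:
        return {"gain": 1, "loss": -1, "none": 0}[self.direction]
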