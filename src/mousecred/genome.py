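"""Genome and chromosome-arm geometry.

A :class:`GenomeLayout` describes chromosome lengths and arm intervals for one
species.  Mouse autosomes are telocentric, so each mouse chromosome is modelled
as a single arm spanning the whole chromosome; human layouts carry p/q arms
taken from a cytoband-derived table.  Coordinates are 0-based half-open
throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class LayoutError(ValueError):
    """A layout or window violates a geometric invariant."""


@dataclass(frozen=True)
class Arm:
    """One chromosome arm: a half-open interval on a chromosome."""

    arm: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise LayoutError(
                f"arm {self.arm}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GenomeLayout:
    """Chromosome lengths plus arm intervals for one species.

    Parameters
    ----------
    species:
        Free-text species tag, e.g. ``"mouse"`` or ``"human"``.
    chrom_lengths:
        Mapping chromosome id -> length in bp.
    arms:
        Arm records; must be disjoint and lie within their chromosome.
    """

    species: str
    chrom_lengths: dict[str, int]
    arms: list[Arm] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, list[Arm]] = {}
        for a in self.arms:
            if a.chrom not in self.chrom_lengths:
                raise LayoutError(f"arm {a.arm}: unknown chromosome {a.chrom!r}")
            if a.end > self.chrom_lengths[a.chrom]:
                raise LayoutError(
                    f"arm {a.arm}: end {a.end} beyond chromosome "
                    f"length {self.chrom_lengths[a.chrom]}"
                )
            seen.setdefault(a.chrom, []).append(a)
        for chrom, chrom_arms in seen.items():
            chrom_arms.sort(key=lambda a: a.start)
            for left, right in zip(chrom_arms, chrom_arms[1:]):
                if right.start < left.end:
                    raise LayoutError(
                        f"arms {left.arm} and {right.arm} overlap on {chrom}"
                    )

    @property
    def arm_ids(self) -> list[str]:
        return [a.arm for a in self.arms]

    def arm(self, arm_id: str) -> Arm:
        for a in self.arms:
            if a.arm == arm_id:
                return a
        raise KeyError(arm_id)

    def arms_on(self, chrom: str) -> list[Arm]:
        return sorted((a for a in self.arms if a.chrom == chrom),
                      key=lambda a: a.start)


@dataclass(frozen=True)
class ArmWindow:
    """Coverage-restricted window of breadth ``c`` centered at an arm midpoint."""

    arm: str
    chrom: str
    c: float
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


# mm10 autosome lengths (bp), the default mouse stated world.
MOUSE_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 195_471_971, "2": 182_113_224, "3": 160_039_680, "4": 156_508_116,
    "5": 151_834_684, "6": 149_736_546, "7": 145_441_459, "8": 129_401_213,
    "9": 124_595_110, "10": 130_694_993, "11": 122_082_543, "12": 120_129_022,
    "13": 120_421_639, "14": 124_902_244, "15": 104_043_685, "16": 98_207_768,
    "17": 94_987_271, "18": 90_702_639, "19": 61_431_566,
}


def mouse_layout(chrom_lengths: dict[str, int] | None = None) -> GenomeLayout:
    """Default mouse layout: 19 autosomes, one whole-chromosome arm each.

    Mouse chromosomes are telocentric (no short arms), so arm == chromosome.
    """
    lengths = dict(chrom_lengths or MOUSE_AUTOSOME_LENGTHS)
    arms = [Arm(arm=c, chrom=c, start=0, end=n) for c, n in lengths.items()]
    return GenomeLayout(species="mouse", chrom_lengths=lengths, arms=arms)


def build_arm_windows(layout: GenomeLayout, c: float) -> list[ArmWindow]:
    """Build one midpoint-centered window of breadth ``c`` per arm.

    The window length is ``round(c * arm_length)``; the start is the floor of
    ``midpoint - length / 2`` and the window is clipped to the arm bounds, so
    ``c = 1`` reproduces the arm exactly.
    """
    if not (0.0 < c <= 1.0):
        raise LayoutError(f"coverage breadth c must be in (0, 1], got {c}")
    windows = []
    for a in layout.arms:
        wlen = round(c * a.length)
        start = int(a.midpoint - wlen / 2.0)  # floor for non-negative values
        end = start + wlen
        start = max(start, a.start)
        end = min(end, a.end)
        windows.append(ArmWindow(arm=a.arm, chrom=a.chrom, c=c,
                                 start=start, end=end))
    return windows


def interval_union_length(intervals: list[tuple[int, int]],
                          clip: tuple[int, int] | None = None) -> int:
    """Total length of the union of half-open intervals, optionally clipped."""
    if clip is not None:
        lo, hi = clip
        intervals = [(max(s, lo), min(e, hi)) for s, e in intervals]
    intervals = sorted((s, e) for s, e in intervals if e > s)
    total = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total
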