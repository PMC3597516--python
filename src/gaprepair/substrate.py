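"""Physical geometry of the gapped recipient locus.

The assay substrate is a plasmid-borne gene carrying a short central gap
that is repaired off a diverged chromosomal template.  Every downstream
stage (simulation, tract calling, classification) reasons about marker
positions only through :class:`SnpMap`: which side of the gap each SNP
lies on, and how far it is from the nearest gap edge.

Coordinates are 1-based and inclusive.  The gap occupies the closed
interval ``[gap_start, gap_start + gap_length - 1]``; a SNP strictly left
of ``gap_start`` is on side LEFT, a SNP at or beyond
``gap_start + gap_length`` is on side RIGHT.  No SNP may fall inside the
gap.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


class Side(enum.Enum):
    """Side of the gap on the recipient locus."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"

    def opposite(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


@dataclass(frozen=True)
class SnpMap:
    """Positions of the gap and the diverged SNP markers.

    Parameters
    ----------
    locus_length
        Length of the recipient locus in bp.
    gap_start
        First deleted position (1-based).
    gap_length
        Number of deleted bp.
    snp_positions
        Strictly increasing 1-based positions of the SNPs; none may lie
        within the gap interval.
    """

    locus_length: int
    gap_start: int
    gap_length: int
    snp_positions: tuple[int, ...]

    def __init__(
        self,
        locus_length: int,
        gap_start: int,
        gap_length: int,
        snp_positions: Sequence[int],
    ) -> None:
        object.__setattr__(self, "locus_length", int(locus_length))
        object.__setattr__(self, "gap_start", int(gap_start))
        object.__setattr__(self, "gap_length", int(gap_length))
        object.__setattr__(self, "snp_positions", tuple(int(p) for p in snp_positions))
        violations = validate_map(self)
        if violations:
            raise ValueError("invalid SnpMap: " + "; ".join(violations))

    # -- derived geometry -------------------------------------------------

    @property
    def gap_end(self) -> int:
        """Last deleted position (1-based, inclusive)."""
        return self.gap_start + self.gap_length - 1

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    @property
    def n_left(self) -> int:
        """Number of SNPs on the LEFT side of the gap."""
        return sum(1 for p in self.snp_positions if p < self.gap_start)

    @property
    def n_right(self) -> int:
        return self.n_snps - self.n_left

    @property
    def left_positions(self) -> tuple[int, ...]:
        return self.snp_positions[: self.n_left]

    @property
    def right_positions(self) -> tuple[int, ...]:
        return self.snp_positions[self.n_left :]

    def distance_to_gap(self, position: int) -> int:
        """bp between a SNP and the nearest gap edge (18 for the anchored SNPs)."""
        if position < self.gap_start:
            return self.gap_start - position
        return position - self.gap_end

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "locus_length": self.locus_length,
            "gap_start": self.gap_start,
            "gap_length": self.gap_length,
            "snp_positions": list(self.snp_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SnpMap":
        return cls(
            locus_length=d["locus_length"],
            gap_start=d["gap_start"],
            gap_length=d["gap_length"],
            snp_positions=d["snp_positions"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SnpMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def validate_map(snp_map: SnpMap) -> list[str]:
    """Return one message per violated :class:`SnpMap` invariant.

    An empty list means the map is structurally valid.  Checks are
    independent so a broken map reports every problem at once.
    """
    v: list[str] = []
    if snp_map.locus_length < 1:
        v.append("locus_length must be positive")
    if snp_map.gap_length < 1:
        v.append("gap_length must be positive")
    if snp_map.gap_start < 1 or snp_map.gap_start + snp_map.gap_length - 1 > snp_map.locus_length:
        v.append("gap not contained in locus")
    positions = snp_map.snp_positions
    if any(b <= a for a, b in zip(positions, positions[1:])):
        v.append("positions not increasing")
    if any(p < 1 or p > snp_map.locus_length for p in positions):
        v.append("snp outside locus")
    gap_lo = snp_map.gap_start
    gap_hi = snp_map.gap_start + snp_map.gap_length - 1
    if any(gap_lo <= p <= gap_hi for p in positions):
        v.append("snp inside gap")
    return v


def side_of(position: int, snp_map: SnpMap) -> Side:
    """Side of the gap for a SNP position in ``snp_map``.

    Raises
    ------
    ValueError
        If ``position`` is not one of the map's SNP positions (in
        particular, if it lies inside the gap).
    """
    if position not in snp_map.snp_positions:
        if snp_map.gap_start <= position <= snp_map.gap_end:
            raise ValueError(f"position {position} lies inside the gap")
        raise ValueError(f"position {position} is not a SNP of this map")
    return Side.LEFT if position < snp_map.gap_start else Side.RIGHT


#: Default geometry: an 800-bp locus with a central 8-bp gap (positions
#: 397-404) and 19 SNPs, the nearest 18 bp from each gap edge.  Only the
#: two anchored SNPs are constrained by the assay design; the remaining
#: 17 are spread deterministically and roughly evenly over the rest of
#: the locus (9 left of the gap at 42-bp spacing, 10 right at 38-bp
#: spacing).  Analyses depend only on side membership and ordering, so
#: any evenly spaced layout is equivalent; override via JSON config for
#: a different substrate.
_DEFAULT_LEFT = tuple(range(43, 380, 42))  # 43 .. 379, 9 SNPs
_DEFAULT_RIGHT = tuple(range(422, 765, 38))  # 422 .. 764, 10 SNPs


def default_substrate() -> SnpMap:
    """The bundled default substrate map (800 bp / 8-bp gap / 19 SNPs)."""
    return SnpMap(
        locus_length=800,
        gap_start=397,
        gap_length=8,
        snp_positions=_DEFAULT_LEFT + _DEFAULT_RIGHT,
    )
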