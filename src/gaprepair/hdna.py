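"""Heteroduplex-DNA tract calling from per-SNP genotype codes.

Each sequenced recombinant yields two genotype strings, one per allele
(the repaired plasmid allele and the chromosomal donor allele).  Every
SNP carries one code:

* ``R`` — the allele's own (recipient) base; no transfer at this SNP,
* ``D`` — the other allele's base; full conversion at this SNP,
* ``H`` — a double peak in the trace; unrepaired heteroduplex that
  segregated at replication (mismatch repair is off in the assay
  background).

A heteroduplex tract is a maximal run of ``H`` codes on one allele.
Runs never span the gap: the gap breaks adjacency, so an allele with
``H`` immediately on both sides of the gap carries two tracts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .substrate import Side, SnpMap

VALID_CODES = frozenset("RDH")


class AlleleRole(enum.Enum):
    PLASMID = "PLASMID"
    CHROMOSOME = "CHROMOSOME"


@dataclass(frozen=True)
class AlleleCalls:
    """Genotype codes for one allele of one recombinant.

    ``codes`` holds one character per SNP of the map, ordered by SNP
    position, with no gap separator.  Use :meth:`from_string` /
    :meth:`to_string` for the serialized form with a literal ``|`` at
    the gap (e.g. ``"RRHHRRRRR|RRRRRRRRRR"``).
    """

    role: AlleleRole
    codes: str

    def __post_init__(self) -> None:
        bad = set(self.codes) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @classmethod
    def from_string(cls, text: str, role: AlleleRole, snp_map: SnpMap) -> "AlleleCalls":
        """Parse a ``LEFT|RIGHT`` code string against a map."""
        if text.count("|") != 1:
            raise ValueError(f"expected exactly one '|' gap separator in {text!r}")
        left, right = text.split("|")
        if len(left) != snp_map.n_left or len(right) != snp_map.n_right:
            raise ValueError(
                f"code string {text!r} has {len(left)}+{len(right)} codes; "
                f"map has {snp_map.n_left}+{snp_map.n_right} SNPs"
            )
        return cls(role=role, codes=left + right)

    def to_string(self, snp_map: SnpMap) -> str:
        self._check_length(snp_map)
        return self.codes[: snp_map.n_left] + "|" + self.codes[snp_map.n_left :]

    def _check_length(self, snp_map: SnpMap) -> None:
        if len(self.codes) != snp_map.n_snps:
            raise ValueError(
                f"{len(self.codes)} codes for a map with {snp_map.n_snps} SNPs"
            )


@dataclass(frozen=True)
class HdnaTract:
    """A maximal run of heteroduplex SNPs on one allele, on one side of the gap.

    ``first_snp_index`` / ``last_snp_index`` are 0-based indices into the
    map's full SNP list (inclusive).
    """

    role: AlleleRole
    side: Side
    first_snp_index: int
    last_snp_index: int

    @property
    def n_snps(self) -> int:
        return self.last_snp_index - self.first_snp_index + 1


@dataclass(frozen=True)
class TransferSummary:
    """Side-level presence flags feeding the mechanism classifier."""

    has_hdna_plasmid_left: bool
    has_hdna_plasmid_right: bool
    has_hdna_chromosome_left: bool
    has_hdna_chromosome_right: bool
    has_conversion: bool

    @property
    def any_transfer(self) -> bool:
        return (
            self.has_hdna_plasmid_left
            or self.has_hdna_plasmid_right
            or self.has_hdna_chromosome_left
            or self.has_hdna_chromosome_right
            or self.has_conversion
        )


def call_tracts(calls: AlleleCalls, snp_map: SnpMap) -> list[HdnaTract]:
    """All maximal H-runs in ``calls``, split at the gap.

    Runs are scanned independently within the left block
    (indices ``0..n_left-1``) and the right block, so a tract can never
    span the gap.  A ``D`` code between two H-runs keeps them separate.
    """
    calls._check_length(snp_map)
    tracts: list[HdnaTract] = []
    blocks = [(0, snp_map.n_left, Side.LEFT), (snp_map.n_left, snp_map.n_snps, Side.RIGHT)]
    for start, stop, side in blocks:
        i = start
        while i < stop:
            if calls.codes[i] == "H":
                j = i
                while j + 1 < stop and calls.codes[j + 1] == "H":
                    j += 1
                tracts.append(
                    HdnaTract(role=calls.role, side=side, first_snp_index=i, last_snp_index=j)
                )
                i = j + 1
            else:
                i += 1
    return tracts


def summarize_transfer(
    plasmid: AlleleCalls, chromosome: AlleleCalls, snp_map: SnpMap
) -> TransferSummary:
    """Collapse both alleles' tracts to the side-level flags used for
    classification.  ``has_conversion`` is true iff either allele carries
    any ``D`` code."""
    if plasmid.role is not AlleleRole.PLASMID or chromosome.role is not AlleleRole.CHROMOSOME:
        raise ValueError("summarize_transfer expects (plasmid, chromosome) in that order")
    p_sides = {t.side for t in call_tracts(plasmid, snp_map)}
    c_sides = {t.side for t in call_tracts(chromosome, snp_map)}
    return TransferSummary(
        has_hdna_plasmid_left=Side.LEFT in p_sides,
        has_hdna_plasmid_right=Side.RIGHT in p_sides,
        has_hdna_chromosome_left=Side.LEFT in c_sides,
        has_hdna_chromosome_right=Side.RIGHT in c_sides,
        has_conversion="D" in plasmid.codes or "D" in chromosome.codes,
    )
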