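"""Plain-text tract maps: one line per sequenced NCO event.

Mirrors the published figure style: events with plasmid heteroduplex
are drawn as a row of per-SNP glyphs, grouped by pattern class and
sorted by tract extent.  Glyphs: ``.`` recipient base, ``o`` converted
(donor base), ``#`` heteroduplex; ``|`` marks the gap.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .classify import MechanismCall
from .simulate import EventRecord
from .substrate import SnpMap

GLYPHS = {"R": ".", "D": "o", "H": "#"}

#: Classes drawn, in display order (only events with plasmid hDNA).
_RENDER_ORDER = [
    MechanismCall.UNIDIRECTIONAL,
    MechanismCall.BIDIRECTIONAL,
    MechanismCall.CLEAVAGE_PATTERN,
]


def _glyph_line(codes_with_sep: str) -> str:
    return "".join("|" if c == "|" else GLYPHS[c] for c in codes_with_sep)


def _extent_key(event: EventRecord, snp_map: SnpMap) -> tuple:
    codes = event.plasmid_calls.replace("|", "")
    h_idx = [i for i, c in enumerate(codes) if c == "H"]
    if not h_idx:
        return (2, 0, 0)
    left_extent = snp_map.n_left - min(h_idx)  # H reach on the left side
    right_extent = max(h_idx) - snp_map.n_left + 1
    # left-side-only events first, widest tracts first within a group
    side_group = 0 if max(h_idx) < snp_map.n_left else (1 if min(h_idx) >= snp_map.n_left else 2)
    return (side_group, -left_extent, -right_extent)


def render_tract_map(
    events: Iterable[EventRecord],
    classes: Mapping[str, MechanismCall],
    snp_map: SnpMap,
) -> str:
    """Render classified events as a deterministic text diagram.

    Parameters
    ----------
    events
        Sequenced event records (must carry code strings).
    classes
        ``event_id -> MechanismCall`` for every event.
    snp_map
        Substrate map defining SNP order and the gap position.
    """
    by_class: dict[MechanismCall, list[EventRecord]] = {c: [] for c in _RENDER_ORDER}
    for e in events:
        call = classes.get(e.event_id)
        if call in by_class:
            by_class[call].append(e)
    lines = []
    header = " " * 14 + "L" * snp_map.n_left + " " + "R" * snp_map.n_right
    lines.append(header)
    for call in _RENDER_ORDER:
        group = sorted(
            by_class[call], key=lambda e: (_extent_key(e, snp_map), e.event_id)
        )
        for e in group:
            lines.append(f"{e.event_id:<8} {call.value[:4]:<4} {_glyph_line(e.plasmid_calls)}")
            if call is MechanismCall.CLEAVAGE_PATTERN:
                lines.append(f"{'':<8} {'chr':<4} {_glyph_line(e.chromosome_calls)}")
    return "\n".join(lines) + "\n"
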