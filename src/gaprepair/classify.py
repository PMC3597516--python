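"""Mechanism-pattern classification of sequenced noncrossover events.

The topology of heteroduplex DNA across the two alleles identifies the
repair route that produced a noncrossover:

* plasmid hDNA on exactly one side, donor clean → **unidirectional**
  (synthesis-dependent strand annealing),
* plasmid hDNA on both sides, donor clean → **bidirectional** (double
  Holliday-junction dissolution, or two independent strand invasions —
  observationally identical),
* plasmid hDNA on one side and donor hDNA on the opposite side →
  **cleavage pattern** (Holliday-junction resolution),
* conversion codes only → **conversion-only**; nothing at all →
  **no-transfer** — both uninformative about the intermediate,
* anything else (e.g. donor hDNA on the same side as plasmid hDNA, or
  donor-only hDNA) → **ambiguous**.

Only unidirectional and bidirectional events enter the class-proportion
denominators downstream; cleavage-pattern events are counted among the
hDNA-detected total but reported separately.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable

import pandas as pd

from .hdna import TransferSummary


class MechanismCall(enum.Enum):
    UNIDIRECTIONAL = "UNIDIRECTIONAL"
    BIDIRECTIONAL = "BIDIRECTIONAL"
    CLEAVAGE_PATTERN = "CLEAVAGE_PATTERN"
    CONVERSION_ONLY = "CONVERSION_ONLY"
    NO_TRANSFER = "NO_TRANSFER"
    AMBIGUOUS = "AMBIGUOUS"


def classify_event(summary: TransferSummary) -> MechanismCall:
    """Classify one noncrossover event from its side-level transfer flags.

    Total and deterministic in the five independent booleans of
    ``summary``; the presence of conversion codes never demotes an event
    that also has heteroduplex (mixed H/D patterns classify by H
    presence).
    """
    p_left, p_right = summary.has_hdna_plasmid_left, summary.has_hdna_plasmid_right
    c_left, c_right = summary.has_hdna_chromosome_left, summary.has_hdna_chromosome_right
    n_plasmid_sides = p_left + p_right
    n_chrom_sides = c_left + c_right

    if not summary.any_transfer:
        return MechanismCall.NO_TRANSFER
    if n_plasmid_sides == 0 and n_chrom_sides == 0:
        return MechanismCall.CONVERSION_ONLY  # has_conversion is true here
    if n_plasmid_sides == 1 and n_chrom_sides == 1:
        opposite = (p_left and c_right) or (p_right and c_left)
        if opposite:
            return MechanismCall.CLEAVAGE_PATTERN
        return MechanismCall.AMBIGUOUS
    if n_chrom_sides == 0:
        if n_plasmid_sides == 2:
            return MechanismCall.BIDIRECTIONAL
        return MechanismCall.UNIDIRECTIONAL
    return MechanismCall.AMBIGUOUS


_COUNT_COLUMNS = {
    MechanismCall.UNIDIRECTIONAL: "unidirectional",
    MechanismCall.BIDIRECTIONAL: "bidirectional",
    MechanismCall.CLEAVAGE_PATTERN: "cleavage",
    MechanismCall.CONVERSION_ONLY: "conversion_only",
    MechanismCall.NO_TRANSFER: "no_transfer",
    MechanismCall.AMBIGUOUS: "ambiguous",
}


def tabulate_classes(events: Iterable[tuple[str, MechanismCall]]) -> pd.DataFrame:
    """Per-strain class counts for a set of classified NCO events.

    Parameters
    ----------
    events
        ``(strain, MechanismCall)`` pairs, one per sequenced event.

    Returns
    -------
    pandas.DataFrame
        Indexed by strain, with one column per class plus
        ``n_sequenced`` (row total) and ``n_with_hdna``
        (unidirectional + bidirectional + cleavage: events with plasmid
        heteroduplex; cleavage events are kept out of the class
        proportions but belong to the detected total).
    """
    counts: dict[str, Counter] = {}
    for strain, call in events:
        counts.setdefault(strain, Counter())[call] += 1
    rows = []
    for strain, c in counts.items():
        row: dict[str, object] = {"strain": strain}
        for call, col in _COUNT_COLUMNS.items():
            row[col] = c.get(call, 0)
        row["n_sequenced"] = sum(c.values())
        row["n_with_hdna"] = (
            c.get(MechanismCall.UNIDIRECTIONAL, 0)
            + c.get(MechanismCall.BIDIRECTIONAL, 0)
            + c.get(MechanismCall.CLEAVAGE_PATTERN, 0)
        )
        rows.append(row)
    if not rows:
        cols = ["strain", *_COUNT_COLUMNS.values(), "n_sequenced", "n_with_hdna"]
        return pd.DataFrame(columns=cols).set_index("strain")
    return pd.DataFrame(rows).set_index("strain")
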