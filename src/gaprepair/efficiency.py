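"""Normalization and efficiency-decomposition arithmetic.

Gap-repair efficiency for one transformation is the His+ : Leu+ colony
ratio, normalized by the wild-type mean ratio for the same plasmid mix.
A strain's repair efficiency (the mean normalized ratio) is then
decomposed multiplicatively:

* CO efficiency  = repair efficiency x CO proportion,
* NCO efficiency = repair efficiency x NCO proportion,
* unidirectional / bidirectional efficiency = NCO efficiency x that
  class's proportion among heteroduplex-detected NCO events.

All chained computations keep full precision; rounding (half-even, two
decimals) happens only at reporting.  Chaining *rounded* intermediates
does not reproduce every published cell, so reported values carry a
documented +/-0.01 tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransformationRecord",
    "NormalizedRatio",
    "CoNcoSplit",
    "normalize_ratios",
    "partition_co_nco",
    "compute_efficiencies",
    "compute_class_efficiencies",
    "build_table",
    "round_report",
    "format_table",
    "TABLE_COLUMNS",
]


@dataclass(frozen=True)
class TransformationRecord:
    """Colony counts from one co-transformation."""

    strain: str
    mix_id: int
    his_count: int
    leu_count: int

    def __post_init__(self) -> None:
        if self.leu_count <= 0:
            raise ValueError("leu_count must be positive")
        if self.his_count < 0:
            raise ValueError("his_count must be nonnegative")

    @property
    def ratio(self) -> float:
        return self.his_count / self.leu_count


@dataclass(frozen=True)
class NormalizedRatio:
    """One transformation's His+:Leu+ ratio divided by the wild-type mean
    ratio of the same plasmid mix."""

    strain: str
    mix_id: int
    value: float


def normalize_ratios(
    records: Sequence[TransformationRecord],
    wt_records: Sequence[TransformationRecord],
    wt_mix_means: Mapping[int, float] | None = None,
) -> list[NormalizedRatio]:
    """Normalize each record's raw ratio by the wild-type mean of its mix.

    Two plasmid mixes were used across experiments and give different
    absolute ratios, so normalization is per ``mix_id`` first; the
    normalized values are then pooled.  ``wt_mix_means`` overrides the
    means computed from ``wt_records`` (e.g. to pin the published 1.57 /
    1.05 values).

    Raises
    ------
    ValueError
        If a record's mix has no wild-type mean available.
    """
    means: dict[int, float] = dict(wt_mix_means or {})
    for mix in {r.mix_id for r in wt_records}:
        if mix not in means:
            vals = [r.ratio for r in wt_records if r.mix_id == mix]
            means[mix] = float(np.mean(vals))
    out = []
    for r in records:
        if r.mix_id not in means:
            raise ValueError(f"no wild-type records or mean for mix {r.mix_id}")
        if means[r.mix_id] <= 0:
            raise ValueError(f"wild-type mean ratio for mix {r.mix_id} is not positive")
        out.append(NormalizedRatio(r.strain, r.mix_id, r.ratio / means[r.mix_id]))
    return out


@dataclass(frozen=True)
class CoNcoSplit:
    co_count: int
    nco_count: int

    @property
    def total(self) -> int:
        return self.co_count + self.nco_count

    @property
    def co_proportion(self) -> float:
        return self.co_count / self.total

    @property
    def nco_proportion(self) -> float:
        return self.nco_count / self.total


def partition_co_nco(stability_calls: Sequence[str]) -> CoNcoSplit:
    """Count CO vs NCO plasmid-stability calls among His+ transformants."""
    if not stability_calls:
        raise ValueError("no stability calls to partition")
    bad = set(stability_calls) - {"CO", "NCO"}
    if bad:
        raise ValueError(f"invalid stability calls: {sorted(bad)}")
    co = sum(1 for c in stability_calls if c == "CO")
    return CoNcoSplit(co_count=co, nco_count=len(stability_calls) - co)


def compute_efficiencies(repair_efficiency: float, co_proportion: float) -> tuple[float, float]:
    """Split repair efficiency into (CO, NCO) efficiencies, full precision."""
    if not 0.0 <= co_proportion <= 1.0:
        raise ValueError("co_proportion must lie in [0, 1]")
    co_eff = repair_efficiency * co_proportion
    return co_eff, repair_efficiency - co_eff


def compute_class_efficiencies(
    nco_efficiency: float,
    uni_count: int,
    bi_count: int,
    n_detected: int | None = None,
) -> tuple[float, float]:
    """Split NCO efficiency into (unidirectional, bidirectional), full precision.

    ``n_detected`` is the heteroduplex-detected denominator; it defaults
    to ``uni_count + bi_count`` but may be larger when rare
    cleavage-pattern events are counted among detected tracts yet kept
    out of the two classes (as in the published double-mutant row).
    """
    if n_detected is None:
        n_detected = uni_count + bi_count
    if n_detected < 1:
        raise ValueError("need at least one heteroduplex-detected event")
    if uni_count + bi_count > n_detected:
        raise ValueError("class counts exceed the detected denominator")
    return (
        nco_efficiency * uni_count / n_detected,
        nco_efficiency * bi_count / n_detected,
    )


def round_report(x: float, ndigits: int = 2) -> float:
    """Half-even rounding on the decimal representation, for reporting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


TABLE_COLUMNS = [
    "repair_efficiency",
    "n_transformations",
    "co_count",
    "nco_count",
    "n_his",
    "co_proportion",
    "nco_proportion",
    "co_efficiency",
    "nco_efficiency",
    "uni_count",
    "bi_count",
    "n_detected",
    "uni_proportion",
    "bi_proportion",
    "uni_efficiency",
    "bi_efficiency",
]


def build_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble the per-strain efficiency table, full precision.

    Each input row needs ``strain``, ``repair_efficiency``, ``co_count``
    and ``n_his`` (total His+ transformants scored for stability);
    optionally ``n_transformations``, ``uni_count``, ``bi_count`` and
    ``n_detected``.  Strains without sequencing data get NaN class
    columns.  Use :func:`format_table` for the rounded reporting view.
    """
    out = []
    seen: set[str] = set()
    for row in rows:
        strain = row["strain"]
        if strain in seen:
            raise ValueError(f"duplicate strain label: {strain}")
        seen.add(strain)
        eff = float(row["repair_efficiency"])
        co, n_his = int(row["co_count"]), int(row["n_his"])
        if not 0 <= co <= n_his or n_his < 1:
            raise ValueError(f"inconsistent CO/total counts for {strain}")
        co_prop = co / n_his
        co_eff, nco_eff = compute_efficiencies(eff, co_prop)
        rec: dict[str, object] = {
            "strain": strain,
            "repair_efficiency": eff,
            "n_transformations": row.get("n_transformations", np.nan),
            "co_count": co,
            "nco_count": n_his - co,
            "n_his": n_his,
            "co_proportion": co_prop,
            "nco_proportion": 1.0 - co_prop,
            "co_efficiency": co_eff,
            "nco_efficiency": nco_eff,
        }
        if row.get("uni_count") is not None and row.get("bi_count") is not None:
            uni, bi = int(row["uni_count"]), int(row["bi_count"])
            nd = row.get("n_detected")
            nd = uni + bi if nd is None else int(nd)
            uni_eff, bi_eff = compute_class_efficiencies(nco_eff, uni, bi, nd)
            rec.update(
                uni_count=uni,
                bi_count=bi,
                n_detected=nd,
                uni_proportion=uni / nd,
                bi_proportion=bi / nd,
                uni_efficiency=uni_eff,
                bi_efficiency=bi_eff,
            )
        else:
            rec.update(
                uni_count=np.nan,
                bi_count=np.nan,
                n_detected=np.nan,
                uni_proportion=np.nan,
                bi_proportion=np.nan,
                uni_efficiency=np.nan,
                bi_efficiency=np.nan,
            )
        out.append(rec)
    return pd.DataFrame(out, columns=["strain", *TABLE_COLUMNS]).set_index("strain")


def format_table(table: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Rounded reporting view of :func:`build_table` output."""
    shown = table.copy()
    for col in shown.columns:
        if col.endswith("efficiency") or col.endswith("proportion"):
            shown[col] = shown[col].map(
                lambda x: np.nan if pd.isna(x) else round_report(x, ndigits)
            )
    return shown
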