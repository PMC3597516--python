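"""Tab-separated interchange formats with provenance headers.

All pipeline artifacts are TSV: a block of ``#``-prefixed provenance
comment lines (tool version, seed, config hash), then a header row, then
records.  ``read_tsv`` round-trips anything ``write_tsv`` produced.
Configs are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .efficiency import TransformationRecord
from .simulate import EventRecord, Mechanism

EVENT_COLUMNS = [
    "event_id",
    "strain",
    "stability_call",
    "plasmid_calls",
    "chromosome_calls",
    "truth_mechanism",
]

TRANSFORMATION_COLUMNS = ["strain", "mix_id", "his_count", "leu_count"]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, **extra: object) -> dict[str, object]:
    prov: dict[str, object] = {"tool": f"gaprepair {__version__}"}
    if seed is not None:
        prov["seed"] = seed
    prov.update(extra)
    return prov


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with ``# key: value`` provenance comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a provenance-commented TSV; empty fields stay empty strings."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


# -- events ---------------------------------------------------------------


def write_events(events: Iterable[EventRecord], path: str | Path, **provenance) -> None:
    df = pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "strain": e.strain,
                "stability_call": e.stability_call,
                "plasmid_calls": e.plasmid_calls,
                "chromosome_calls": e.chromosome_calls,
                "truth_mechanism": e.truth_mechanism.value,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    write_tsv(df, path, provenance_lines(**provenance))


def read_events(path: str | Path) -> list[EventRecord]:
    df = read_tsv(path, required=EVENT_COLUMNS[:5])
    records = []
    for i, row in df.iterrows():
        try:
            mech = Mechanism(row["truth_mechanism"]) if "truth_mechanism" in df.columns else None
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from None
        records.append(
            EventRecord(
                event_id=str(row["event_id"]),
                strain=str(row["strain"]),
                truth_mechanism=mech,
                stability_call=str(row["stability_call"]),
                plasmid_calls=str(row["plasmid_calls"]),
                chromosome_calls=str(row["chromosome_calls"]),
            )
        )
    return records


# -- transformations ------------------------------------------------------


def write_transformations(
    records: Iterable[TransformationRecord], path: str | Path, **provenance
) -> None:
    df = pd.DataFrame(
        [
            {"strain": r.strain, "mix_id": r.mix_id, "his_count": r.his_count, "leu_count": r.leu_count}
            for r in records
        ],
        columns=TRANSFORMATION_COLUMNS,
    )
    write_tsv(df, path, provenance_lines(**provenance))


def read_transformations(path: str | Path) -> list[TransformationRecord]:
    df = read_tsv(path, required=TRANSFORMATION_COLUMNS)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                TransformationRecord(
                    strain=str(row["strain"]),
                    mix_id=int(row["mix_id"]),
                    his_count=int(row["his_count"]),
                    leu_count=int(row["leu_count"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from None
    return out


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """CLI run configuration (JSON on disk)."""

    map_path: str | None = None
    seed: int = 0
    strain: str = "WT"
    wt_strain: str = "WT"
    wt_mix_means: dict[int, float] = field(default_factory=dict)
    welch: bool = False
    mmr_repair_prob: float = 0.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "wt_mix_means" in kwargs:
            kwargs["wt_mix_means"] = {int(k): float(v) for k, v in kwargs["wt_mix_means"].items()}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")
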