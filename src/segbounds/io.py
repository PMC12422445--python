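"""Reading, writing and validating boundary-annotation datasets.

The canonical on-disk form is a single JSON object::

    {
      "provenance": "<free text>",
      "pieces": {"<piece_id>": <duration_s>, ...},
      "annotations": [
        {"participant_id": ..., "piece_id": ..., "condition": "AP",
         "time_s": 12.345, "level": 3, "label": null},
        ...
      ]
    }

Condition tokens name the modalities present while annotating: ``A`` audio,
``P`` piano roll, ``W`` waveform, and their combinations (``APW``, ``AP``,
``AW``, ``PW``).  Strength levels run from 1 (weakest) to 4 (strongest).
Externally produced files with different key spellings or condition tokens
are adapted through a :class:`FieldMap` rather than guessed at.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: The seven raw experimental conditions.
CONDITIONS: tuple[str, ...] = ("APW", "AP", "AW", "PW", "P", "W", "A")

#: Valid boundary strength levels, weakest to strongest.
LEVELS: tuple[int, ...] = (1, 2, 3, 4)

#: Timestamps are stored with millisecond precision; sub-second placement
#: is meaningful but finer digits are annotation-interface noise.
TIME_DECIMALS = 3


@dataclass(frozen=True)
class Annotation:
    """One placed boundary: who, where, under which condition, when, how strong."""

    participant_id: str
    piece_id: str
    condition: str
    time_s: float
    level: int
    label: str | None = None

    def sort_key(self) -> tuple:
        return (self.participant_id, self.piece_id, self.time_s, self.level)


@dataclass
class ValidationReport:
    """Per-record diagnostics from a load: nothing is dropped silently."""

    n_input: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (record index, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class AnnotationDataset:
    """A collection of annotations plus the piece-duration table.

    This is the unit that flows through outlier filtering and condition
    pooling.  Invariants: every annotation references a known piece, lies
    within that piece's duration, uses a level in 1-4 and a known condition
    token, and no exact (participant, piece, time, level) duplicate exists.
    """

    annotations: list[Annotation]
    pieces: dict[str, float]
    provenance: str = ""
    validation: ValidationReport | None = None

    def __len__(self) -> int:
        return len(self.annotations)

    def participants(self) -> list[str]:
        return sorted({a.participant_id for a in self.annotations})

    def to_frame(self) -> pd.DataFrame:
        """Annotations as a tidy DataFrame (one row per boundary)."""
        return pd.DataFrame(
            [
                {
                    "participant_id": a.participant_id,
                    "piece_id": a.piece_id,
                    "condition": a.condition,
                    "time_s": a.time_s,
                    "level": a.level,
                    "label": a.label,
                }
                for a in self.annotations
            ],
            columns=["participant_id", "piece_id", "condition", "time_s", "level", "label"],
        )

    def validate(self) -> None:
        """Raise :class:`SchemaError` on the first invariant violation."""
        seen = set()
        for a in self.annotations:
            _check_record(a, self.pieces)
            key = a.sort_key()
            if key in seen:
                raise SchemaError(f"duplicate annotation record {key}")
            seen.add(key)


@dataclass(frozen=True)
class FieldMap:
    """Adapter from an external file's spellings to the canonical schema.

    ``keys`` maps canonical field names (participant_id, piece_id, condition,
    time_s, level, label) to the names used in the external file;
    ``conditions`` maps external condition tokens to the canonical seven;
    ``pieces_key``/``annotations_key`` name the top-level containers.
    """

    keys: Mapping[str, str] = field(default_factory=dict)
    conditions: Mapping[str, str] = field(default_factory=dict)
    pieces_key: str = "pieces"
    annotations_key: str = "annotations"
    provenance_key: str = "provenance"

    def field_name(self, canonical: str) -> str:
        return self.keys.get(canonical, canonical)

    def condition(self, token: str) -> str:
        return self.conditions.get(token, token)


def _check_record(a: Annotation, pieces: Mapping[str, float]) -> None:
    if a.condition not in CONDITIONS:
        raise SchemaError(f"unknown condition token {a.condition!r}")
    if a.piece_id not in pieces:
        raise SchemaError(f"piece {a.piece_id!r} has no duration entry")
    if a.level not in LEVELS:
        raise SchemaError(f"level {a.level} outside 1-4")
    if not (0.0 <= a.time_s <= pieces[a.piece_id]):
        raise SchemaError(
            f"time {a.time_s} s outside [0, {pieces[a.piece_id]}] for piece {a.piece_id!r}"
        )


def load_dataset(path: str | Path, field_map: FieldMap | None = None) -> AnnotationDataset:
    """Load and validate an annotation dataset from JSON.

    Out-of-range records are rejected individually with a diagnostic naming
    the record; the counts satisfy n_input = n_kept + n_rejected and are
    available on ``dataset.validation``.  A missing piece duration or an
    unresolvable condition token rejects the record.
    """
    fm = field_map or FieldMap()
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if fm.pieces_key not in raw:
        raise SchemaError(f"top-level {fm.pieces_key!r} object missing in {path}")
    pieces = {str(k): float(v) for k, v in raw[fm.pieces_key].items()}
    for pid, dur in pieces.items():
        if dur <= 0:
            raise SchemaError(f"piece {pid!r} has non-positive duration {dur}")

    report = ValidationReport()
    kept: list[Annotation] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(raw.get(fm.annotations_key, [])):
        report.n_input += 1
        try:
            ann = Annotation(
                participant_id=str(rec[fm.field_name("participant_id")]),
                piece_id=str(rec[fm.field_name("piece_id")]),
                condition=fm.condition(str(rec[fm.field_name("condition")])),
                time_s=round(float(rec[fm.field_name("time_s")]), TIME_DECIMALS),
                level=int(rec[fm.field_name("level")]),
                label=rec.get(fm.field_name("label")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            report.rejected.append((i, f"record {i}: malformed ({exc!r})"))
            continue
        try:
            _check_record(ann, pieces)
        except SchemaError as exc:
            report.rejected.append((i, f"record {i}: {exc}"))
            continue
        key = ann.sort_key()
        if key in seen:
            report.rejected.append((i, f"record {i}: duplicate of {key}"))
            continue
        seen.add(key)
        kept.append(ann)
    report.n_kept = len(kept)

    for reason in (r for _, r in report.rejected):
        logger.warning("rejected %s", reason)
    counts = Counter((a.condition, a.piece_id) for a in kept)
    logger.info(
        "loaded %d annotations (%d rejected) over %d pieces, %d condition/piece cells",
        report.n_kept, report.n_rejected, len(pieces), len(counts),
    )
    return AnnotationDataset(
        annotations=sorted(kept, key=Annotation.sort_key),
        pieces=pieces,
        provenance=str(raw.get(fm.provenance_key, "")),
        validation=report,
    )


def write_dataset(dataset: AnnotationDataset, path: str | Path) -> None:
    """Write the canonical JSON form: sorted keys, stable record order, UTF-8.

    Two writes of the same dataset are byte-identical, so outputs diff cleanly.
    """
    records = []
    for a in sorted(dataset.annotations, key=Annotation.sort_key):
        records.append(
            {
                "participant_id": a.participant_id,
                "piece_id": a.piece_id,
                "condition": a.condition,
                "time_s": round(a.time_s, TIME_DECIMALS),
                "level": a.level,
                "label": a.label,
            }
        )
    doc = {
        "provenance": dataset.provenance,
        "pieces": {k: dataset.pieces[k] for k in sorted(dataset.pieces)},
        "annotations": records,
    }
    text = json.dumps(doc, sort_keys=True, ensure_ascii=False, indent=1)
    Path(path).write_text(text + "\n", encoding="utf-8")


def write_piece_table(pieces: Mapping[str, float], path: str | Path) -> None:
    """Piece metadata as CSV with header ``piece_id,duration_s``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["piece_id", "duration_s"])
        for pid in sorted(pieces):
            writer.writerow([pid, pieces[pid]])


def load_piece_table(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, dtype={"piece_id": str})
    if not {"piece_id", "duration_s"} <= set(frame.columns):
        raise SchemaError(f"{path}: expected columns piece_id,duration_s")
    return dict(zip(frame["piece_id"], frame["duration_s"].astype(float)))
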