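"""Outlier removal by the IQR upper-outer-fence rule, and condition pooling.

Some annotators place an atypical number of boundaries — typically because
they used a single strength level throughout or ignored the instructions.
For each strength level, the per-participant boundary counts (aggregated over
all pieces the participant annotated) are compared against the upper outer
fence Q3 + 3*IQR; a participant above the fence has *all* their boundaries at
that level removed, leaving the other levels untouched.

Quartiles use linear interpolation between order statistics (numpy's default,
the "type 7" rule); the fence is sensitive to this convention, so it is fixed
and documented here rather than configurable.

Pooling maps the seven raw conditions onto five grouped ones:
AV <- {APW, AP, AW} (audio plus any visuals), A <- {A}, V <- {PW} (both
visuals), P <- {P}, W <- {W}.  Pooling concatenates different participant
groups' data; no annotation is duplicated or dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .io import Annotation, AnnotationDataset, LEVELS

#: Grouped-condition membership: raw token -> grouped name.
CONDITION_GROUPS: dict[str, str] = {
    "APW": "AV",
    "AP": "AV",
    "AW": "AV",
    "PW": "V",
    "P": "P",
    "W": "W",
    "A": "A",
}

#: The five grouped conditions in display order.
GROUPED_CONDITIONS: tuple[str, ...] = ("AV", "A", "V", "P", "W")

#: Fence multiplier for the *outer* fence (inner would be 1.5).
FENCE_MULTIPLIER = 3.0


@dataclass
class OutlierReport:
    """What the fence rule examined and removed, sufficient to audit the run."""

    removed_pairs: list[tuple[str, int]] = field(default_factory=list)
    fence_by_level: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    counts_examined: dict[tuple[str, int], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per (participant, level): count, fence, removed flag."""
        removed = set(self.removed_pairs)
        rows = [
            {
                "participant_id": pid,
                "level": level,
                "count": count,
                "fence": self.fence_by_level[level][2],
                "removed": (pid, level) in removed,
            }
            for (pid, level), count in sorted(self.counts_examined.items())
        ]
        return pd.DataFrame(rows, columns=["participant_id", "level", "count", "fence", "removed"])


def upper_outer_fence(counts: np.ndarray, multiplier: float = FENCE_MULTIPLIER) -> tuple[float, float, float]:
    """(Q3, IQR, fence) of a count distribution under the type-7 quartile rule."""
    q1, q3 = np.quantile(counts, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return float(q3), float(iqr), float(q3 + multiplier * iqr)


def remove_outliers(
    dataset: AnnotationDataset, multiplier: float = FENCE_MULTIPLIER
) -> tuple[AnnotationDataset, OutlierReport]:
    """Drop each (participant, level) whose boundary count exceeds the fence.

    The count distribution at each level runs over *all* participants present
    in the dataset, with zero counts for participants who never used that
    level.  Removal deletes every annotation of that participant at that
    level; the decision is participant-global, not per piece.
    """
    report = OutlierReport()
    participants = dataset.participants()
    if not participants:
        return dataset, report

    counts: dict[tuple[str, int], int] = defaultdict(int)
    for a in dataset.annotations:
        counts[(a.participant_id, a.level)] += 1

    removed: set[tuple[str, int]] = set()
    for level in LEVELS:
        level_counts = np.array([counts.get((p, level), 0) for p in participants], dtype=float)
        q3, iqr, fence = upper_outer_fence(level_counts, multiplier)
        report.fence_by_level[level] = (q3, iqr, fence)
        for p in participants:
            c = counts.get((p, level), 0)
            report.counts_examined[(p, level)] = c
            if c > fence:
                removed.add((p, level))

    report.removed_pairs = sorted(removed)
    kept = [a for a in dataset.annotations if (a.participant_id, a.level) not in removed]
    filtered = AnnotationDataset(
        annotations=kept,
        pieces=dict(dataset.pieces),
        provenance=dataset.provenance,
    )
    return filtered, report


def pool_conditions(
    dataset: AnnotationDataset,
) -> dict[tuple[str, str], list[Annotation]]:
    """Pool raw conditions into grouped ones: (piece_id, group) -> annotations.

    Every annotation lands in exactly one grouped condition, so the total
    count is conserved.
    """
    pooled: dict[tuple[str, str], list[Annotation]] = defaultdict(list)
    for a in dataset.annotations:
        try:
            group = CONDITION_GROUPS[a.condition]
        except KeyError:
            raise SchemaError(f"unknown condition token {a.condition!r}") from None
        pooled[(a.piece_id, group)].append(a)
    return dict(pooled)
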