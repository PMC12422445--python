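"""Shared builders for the test suite.

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from segbounds.io import Annotation, AnnotationDataset
from segbounds.profiles import BoundaryProfile


def make_profile(weights, bin_width_s: float = 1.0, piece: str = "p0", group: str = "AV"):
    """A profile straight from a weight vector, one grid unit per bin."""
    w = np.asarray(weights, dtype=float)
    return BoundaryProfile(
        piece_id=piece,
        group=group,
        bin_width_s=bin_width_s,
        weights=w,
        duration_s=len(w) * bin_width_s,
    )


def random_sparse_weights(
    rng: np.random.Generator, n_bins: int, max_occupied: int
) -> np.ndarray:
    """Nonnegative integer masses on a few random bins (at least one occupied)."""
    w = np.zeros(n_bins)
    n_occ = int(rng.integers(1, max_occupied + 1))
    idx = rng.choice(n_bins, size=min(n_occ, n_bins), replace=False)
    w[idx] = rng.integers(1, 5, size=len(idx))
    return w


def make_dataset(records, pieces) -> AnnotationDataset:
    """Dataset from (participant, piece, condition, time, level) tuples."""
    return AnnotationDataset(
        annotations=[Annotation(*rec) for rec in records],
        pieces=dict(pieces),
        provenance="test",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
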