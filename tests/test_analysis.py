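"""Comparison tables, rankings, statistics, per-piece ranks and MDS."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from segbounds.analysis import (
    COMPARISONS,
    AnalysisConfig,
    classical_mds,
    describe,
    mds_embed,
    per_piece_ranks,
    profile_distance_matrix,
    rank_comparisons,
    run_comparisons,
)
from segbounds.io import Annotation
from segbounds.profiles import build_profile
from segbounds.transport import uot_distance

from conftest import make_profile


def pooled_data(pieces, jitter_by_group=None, rng=None):
    """Synthetic pooled annotations: same skeleton per group, optional jitter."""
    jitter_by_group = jitter_by_group or {}
    rng = rng or np.random.default_rng(0)
    pooled = {}
    for piece, duration in pieces.items():
        base = np.linspace(0.1 * duration, 0.9 * duration, 5)
        for group in ("AV", "A", "V", "P", "W"):
            sd = jitter_by_group.get(group, 0.0)
            times = np.clip(base + rng.normal(0, sd, len(base)) if sd else base, 0, duration)
            pooled[(piece, group)] = [
                Annotation(f"q{i}", piece, "APW", float(t), 1 + i % 4)
                for i, t in enumerate(times)
            ]
    return pooled


class TestComparisonTable:
    def test_shape_and_labels(self):
        pieces = {"a": 30.0, "b": 40.0}
        table = run_comparisons(pooled_data(pieces), pieces, "uot")
        assert table.values.shape == (2, 7)
        assert list(table.values.columns) == [c.label for c in COMPARISONS]

    def test_identical_groups_give_zero_uot_everywhere(self):
        pieces = {"a": 30.0}
        table = run_comparisons(pooled_data(pieces), pieces, "uot")
        assert np.allclose(table.values.to_numpy(), 0.0)

    def test_cell_equals_direct_transport_call(self):
        pieces = {"a": 30.0}
        pooled = pooled_data(pieces, jitter_by_group={"A": 1.0, "W": 0.5})
        cfg = AnalysisConfig()
        table = run_comparisons(pooled, pieces, "uot", cfg)
        f = build_profile(pooled[("a", "AV")], 30.0, cfg.bin_width_s, cfg.level_weighting)
        g = build_profile(pooled[("a", "A")], 30.0, cfg.bin_width_s, cfg.level_weighting)
        direct = uot_distance(f, g, cfg.cost_c).scaled_distance
        assert table.values.loc["a", "AV vs A"] == pytest.approx(direct)

    def test_empty_side_leaves_cell_missing(self):
        pieces = {"a": 30.0}
        pooled = pooled_data(pieces)
        pooled.pop(("a", "W"))
        table = run_comparisons(pooled, pieces, "uot")
        assert np.isnan(table.values.loc["a", "AV vs W"])
        assert np.isnan(table.values.loc["a", "A vs W"])
        assert not table.values.drop(columns=["AV vs W", "A vs W"]).isna().any().any()

    def test_unknown_metric_rejected(self):
        from segbounds.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            run_comparisons({}, {}, "hausdorff")


class TestRanking:
    def make_table(self, values, pieces=None):
        from segbounds.analysis import ComparisonTable

        frame = pd.DataFrame(
            values, columns=[c.label for c in COMPARISONS],
            index=pieces or [f"p{i}" for i in range(len(values))],
        )
        return ComparisonTable(metric="uot", values=frame, config=AnalysisConfig())

    def test_uniformly_smallest_comparison_ranks_first(self):
        rows = [[0.1, 1, 2, 3, 4, 5, 6], [0.2, 6, 5, 4, 3, 2, 1]]
        ranking = rank_comparisons(self.make_table(rows))
        assert ranking.iloc[0]["comparison"] == "AV vs V"
        assert ranking.iloc[0]["ranking"] == 1

    def test_invariant_to_piece_order(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(0, 1, size=(6, 7))
        a = rank_comparisons(self.make_table(list(rows)))
        b = rank_comparisons(self.make_table(list(rows[::-1])))
        pd.testing.assert_frame_equal(a, b)

    def test_describe_constant_table(self):
        stats = describe(self.make_table([[2.0] * 7] * 3))
        assert stats["mean"] == stats["median"] == stats["min"] == stats["max"] == 2.0
        assert stats["std"] == 0.0
        assert stats["count"] == 21

    def test_describe_counts_all_cells(self):
        rng = np.random.default_rng(1)
        stats = describe(self.make_table(list(rng.uniform(size=(5, 7)))))
        assert stats["count"] == 35

    def test_per_piece_ranks_strictly_increasing_row(self):
        ranks, tally = per_piece_ranks(self.make_table([[1, 2, 3, 4, 5, 6, 7]]))
        assert list(ranks.iloc[0]) == [1, 2, 3, 4, 5, 6, 7]
        assert tally["smallest"].sum() == 1 and tally["largest"].sum() == 1

    def test_rank_one_tallies_sum_to_piece_count(self):
        rng = np.random.default_rng(2)
        _, tally = per_piece_ranks(self.make_table(list(rng.uniform(size=(9, 7)))))
        assert tally["smallest"].sum() == 9
        assert tally["largest"].sum() == 9

    def test_ties_share_the_smaller_rank(self):
        ranks, tally = per_piece_ranks(self.make_table([[0.5, 0.5, 1, 2, 3, 4, 5]]))
        assert list(ranks.iloc[0][:3]) == [1, 1, 3]
        # tie-break by comparison id: the first column takes the tally
        assert tally.loc["AV vs V", "smallest"] == 1
        assert tally.loc["A vs V", "smallest"] == 0


class TestMds:
    def test_equilateral_triangle_embeds_exactly(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        coords, stress, dim = classical_mds(D)
        emb = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        off = emb[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0, atol=1e-6)
        assert stress < 1e-6
        assert dim == 2

    def test_zero_distances_collapse_to_origin(self):
        coords, stress, _ = classical_mds(np.zeros((4, 4)))
        assert np.allclose(coords, 0.0)
        assert stress == 0.0

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        a, _, _ = classical_mds(D)
        b, _, _ = classical_mds(D)
        assert np.array_equal(a, b)
        for axis in a.T:
            assert axis[np.argmax(np.abs(axis))] >= 0

    def test_recovered_distances_correlate_on_clustered_profiles(self):
        # three clusters of profiles with peaks at distinct locations
        rng = np.random.default_rng(11)
        profiles = []
        for c, centre in enumerate((10, 45, 80)):
            for i in range(4):
                w = np.zeros(100)
                for _ in range(6):
                    w[int(np.clip(centre + rng.normal(0, 3), 0, 99))] += rng.integers(1, 5)
                profiles.append(make_profile(w, piece=f"c{c}", group="AV"))
        D = profile_distance_matrix(profiles, cost_c=2.0)
        coords, _, _ = classical_mds(D)
        emb = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(profiles), 1)
        rho = spearmanr(D[iu], emb[iu]).statistic
        assert rho >= 0.9

    def test_mds_embed_returns_labelled_frame(self):
        profiles = [make_profile([1, 0, 0], piece="a", group="AV"),
                    make_profile([0, 1, 0], piece="a", group="V"),
                    make_profile([0, 0, 2], piece="b", group="A")]
        coords, stress = mds_embed(profiles)
        assert set(coords.columns) == {"piece_id", "group", "dim1", "dim2"}
        assert len(coords) == 3
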