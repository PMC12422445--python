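"""Tests of the synthetic annotation generator: design, noise model, determinism."""

import numpy as np
import pytest
from scipy import stats

from segbounds.errors import ConfigurationError, DesignError
from segbounds.io import CONDITIONS
from segbounds.synthetic import (
    PieceTemplate,
    SimulationConfig,
    TrueBoundary,
    assign_conditions,
    combined_salience,
    condition_modalities,
    generate_templates,
    planted_spammers,
    simulate_annotations,
    simulate_study,
)

MODS = ("audio", "pianoroll", "waveform")


def uniform_config(**overrides) -> SimulationConfig:
    """A clean config: deterministic detection, no noise of any kind."""
    base = dict(
        n_pieces=3,
        jitter_sd_s={m: 0.0 for m in MODS},
        salience_by_level={m: (1.0, 1.0, 1.0, 1.0) for m in MODS},
        audio_only_shift_s=0.0,
        spurious_rate_per_min=0.0,
        level_confusion_prob=0.0,
        spammer_fraction=0.0,
        rng_seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestTemplates:
    def test_count_and_durations(self):
        templates = generate_templates(SimulationConfig(n_pieces=33, rng_seed=1))
        assert len(templates) == 33
        assert all(t.duration_s > 0 for t in templates)
        assert all(len(t.true_boundaries) >= 2 for t in templates)

    def test_seeded_determinism(self):
        a = generate_templates(SimulationConfig(n_pieces=1, rng_seed=7))
        b = generate_templates(SimulationConfig(n_pieces=1, rng_seed=7))
        assert a == b

    def test_salience_monotone_in_level_within_template(self):
        # a stronger boundary is never harder to detect in any channel
        for t in generate_templates(SimulationConfig(n_pieces=10, rng_seed=3)):
            for b1 in t.true_boundaries:
                for b2 in t.true_boundaries:
                    if b1.true_level < b2.true_level:
                        assert all(b1.salience[m] <= b2.salience[m] for m in MODS)

    def test_times_strictly_increasing_within_duration(self):
        for t in generate_templates(SimulationConfig(n_pieces=10, rng_seed=4)):
            times = [b.time_s for b in t.true_boundaries]
            assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
            assert 0 <= times[0] and times[-1] <= t.duration_s

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_templates(SimulationConfig(n_pieces=0))

    def test_template_invariants_enforced(self):
        sal = {m: 0.5 for m in MODS}
        with pytest.raises(ConfigurationError):
            PieceTemplate("x", 10.0, (TrueBoundary(5.0, 2, sal), TrueBoundary(5.0, 3, sal)))
        with pytest.raises(ConfigurationError):
            PieceTemplate("x", 10.0, (TrueBoundary(11.0, 2, sal),))


class TestLatinSquare:
    def test_square_design_covers_every_pair_once(self):
        config = SimulationConfig(n_pieces=7, rng_seed=0)
        pieces = generate_templates(config)
        assignment = assign_conditions(pieces, config)
        for piece in pieces:
            seen = [assignment[g][piece.piece_id] for g in range(7)]
            assert sorted(seen) == sorted(CONDITIONS)

    def test_group_condition_counts_balanced(self):
        config = SimulationConfig(n_pieces=33, rng_seed=0)
        pieces = generate_templates(config)
        assignment = assign_conditions(pieces, config)
        for g in range(7):
            counts = {c: 0 for c in CONDITIONS}
            for cond in assignment[g].values():
                counts[cond] += 1
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_wrong_group_count_is_design_error(self):
        config = SimulationConfig(n_pieces=7, n_groups=6, rng_seed=0)
        pieces = generate_templates(SimulationConfig(n_pieces=7, rng_seed=0))
        with pytest.raises(DesignError):
            assign_conditions(pieces, config)


class TestSimulation:
    def test_noiseless_limit_reproduces_templates(self):
        config = uniform_config()
        templates = generate_templates(config)
        assignment = assign_conditions(templates, config)
        dataset = simulate_annotations(templates, assignment, config)
        by_pp = {}
        for a in dataset.annotations:
            by_pp.setdefault((a.participant_id, a.piece_id), []).append(a)
        assert len(by_pp) == config.n_participants * config.n_pieces
        by_id = {t.piece_id: t for t in templates}
        for (_, piece_id), anns in by_pp.items():
            template = by_id[piece_id]
            got = sorted((a.time_s, a.level) for a in anns)
            want = sorted(
                (round(b.time_s, 3), b.true_level) for b in template.true_boundaries
            )
            assert got == want

    def test_zero_salience_yields_empty_dataset(self):
        config = uniform_config(salience_by_level={m: (0.0,) * 4 for m in MODS})
        templates = generate_templates(config)
        dataset = simulate_annotations(templates, assign_conditions(templates, config), config)
        assert len(dataset) == 0

    def test_detection_rate_matches_bernoulli_model(self):
        # ~10^4 participant-boundary trials under audio-only at salience 0.9
        config = uniform_config(
            n_pieces=1,
            participants_per_group=180,
            salience_by_level={
                "audio": (0.9,) * 4, "pianoroll": (0.5,) * 4, "waveform": (0.5,) * 4
            },
            rng_seed=11,
        )
        template = generate_templates(config)[0]
        assignment = {g: {template.piece_id: "A"} for g in range(7)}
        dataset = simulate_annotations([template], assignment, config)
        n_trials = config.n_participants * len(template.true_boundaries)
        assert n_trials >= 10_000
        rate = len(dataset) / n_trials
        se = np.sqrt(0.9 * 0.1 / n_trials)
        assert abs(rate - 0.9) <= 3 * se

    def test_noisy_or_goodness_of_fit(self):
        # per-boundary detection counts under AP vs the noisy-OR rule,
        # chi-square GOF not rejected at alpha = 0.01
        config = uniform_config(
            n_pieces=1,
            participants_per_group=180,
            salience_by_level={
                "audio": (0.3, 0.4, 0.5, 0.6),
                "pianoroll": (0.5, 0.6, 0.7, 0.8),
                "waveform": (0.5, 0.6, 0.7, 0.8),
            },
            rng_seed=13,
        )
        template = generate_templates(config)[0]
        assignment = {g: {template.piece_id: "AP"} for g in range(7)}
        dataset = simulate_annotations([template], assignment, config)
        n = config.n_participants
        mods = condition_modalities("AP")
        chi2 = 0.0
        for b in template.true_boundaries:
            p = combined_salience(b, mods)
            k = sum(1 for a in dataset.annotations if abs(a.time_s - b.time_s) < 1e-3)
            chi2 += (k - n * p) ** 2 / (n * p * (1 - p))
        pvalue = stats.chi2.sf(chi2, df=len(template.true_boundaries))
        assert pvalue > 0.01

    def test_spammers_use_single_level_and_flood(self):
        config = SimulationConfig(n_pieces=2, spammer_fraction=0.1, rng_seed=5)
        templates = generate_templates(config)
        dataset = simulate_annotations(templates, assign_conditions(templates, config), config)
        spammers = planted_spammers(config)
        assert spammers  # 10% of 56
        by_id = {t.piece_id: t for t in templates}
        for participant, level in spammers.items():
            anns = [a for a in dataset.annotations if a.participant_id == participant]
            assert anns and all(a.level == level for a in anns)
            for t in templates:
                per_piece = [a for a in anns if a.piece_id == t.piece_id]
                assert len(per_piece) >= 5 * len(by_id[t.piece_id].true_boundaries) - 2

    def test_times_clamped_to_piece(self):
        dataset = simulate_study(SimulationConfig(n_pieces=5, rng_seed=9))
        for a in dataset.annotations:
            assert 0.0 <= a.time_s <= dataset.pieces[a.piece_id]

    def test_full_simulation_bit_reproducible(self):
        a = simulate_study(SimulationConfig(n_pieces=4, rng_seed=21))
        b = simulate_study(SimulationConfig(n_pieces=4, rng_seed=21))
        assert a.annotations == b.annotations and a.pieces == b.pieces
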