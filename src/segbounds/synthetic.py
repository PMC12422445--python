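"""Synthetic boundary-annotation datasets with the study's statistical structure.

The generator emulates a segmentation-annotation experiment: a set of short
musical pieces, each carrying a template of "true" boundaries with graded
strengths, annotated by participants working under one of seven audiovisual
conditions (audio A, piano roll P, waveform W, and combinations).  Participants
form seven groups of eight; a Latin square assigns one condition per
(group, piece) so every piece is annotated under every condition by exactly
one group.

Noise model, per participant and piece:

* each true boundary is detected independently with probability
  ``1 - prod(1 - s_m)`` over the modalities m present in the condition
  (noisy-OR: adding a modality never hurts detection);
* a detected boundary's reported time is the true time plus Gaussian jitter
  whose standard deviation is the largest jitter among present modalities,
  plus a constant early/late bias in the audio-only condition (listeners
  tend to mark peaks earlier than readers of the visuals);
* the reported level equals the true level, perturbed by +-1 with a small
  confusion probability and clamped to 1-4;
* spurious boundaries arrive as a Poisson process (rate per minute) with
  uniform times and levels;
* a small fraction of participants are "spammers": they use a single level
  for everything and place at least five times as many boundaries as the
  template holds, which is what the downstream outlier fence must catch.

No quantitative noise magnitudes were measured for human annotators; the
defaults below are stand-ins chosen to look like plausible human timing and
detection behaviour, not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DesignError
from .io import Annotation, AnnotationDataset, CONDITIONS, LEVELS

#: Modalities a condition token can contain.
MODALITIES: tuple[str, ...] = ("audio", "pianoroll", "waveform")

_TOKEN_TO_MODALITIES: dict[str, frozenset[str]] = {
    "APW": frozenset({"audio", "pianoroll", "waveform"}),
    "AP": frozenset({"audio", "pianoroll"}),
    "AW": frozenset({"audio", "waveform"}),
    "PW": frozenset({"pianoroll", "waveform"}),
    "P": frozenset({"pianoroll"}),
    "W": frozenset({"waveform"}),
    "A": frozenset({"audio"}),
}


def condition_modalities(condition: str) -> frozenset[str]:
    """The set of modalities present under a raw condition token."""
    try:
        return _TOKEN_TO_MODALITIES[condition]
    except KeyError:
        raise ConfigurationError(f"unknown condition token {condition!r}") from None


@dataclass(frozen=True)
class TrueBoundary:
    """A template boundary: when it occurs, how strong it is, how detectable."""

    time_s: float
    true_level: int
    salience: Mapping[str, float]  # per-modality detection probability


@dataclass(frozen=True)
class PieceTemplate:
    """Ground truth for one piece: duration plus ordered graded boundaries."""

    piece_id: str
    duration_s: float
    true_boundaries: tuple[TrueBoundary, ...]

    def __post_init__(self) -> None:
        times = [b.time_s for b in self.true_boundaries]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigurationError("template boundary times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration_s):
            raise ConfigurationError("template boundary outside [0, duration]")
        for b in self.true_boundaries:
            if not all(0.0 <= b.salience[m] <= 1.0 for m in MODALITIES):
                raise ConfigurationError("salience probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study.

    Defaults reproduce the study scale: 33 pieces, 7 groups x 8 participants,
    7 conditions assigned as a Latin square.  Detection probabilities per
    strength level are higher for the visual channels than for audio, so
    audio-only annotators miss more of the visually salient structure; the
    visual channels are faithful in time while audio carries broader jitter
    and an early bias — the asymmetry the study observed between modalities.
    """

    n_pieces: int = 33
    participants_per_group: int = 8
    n_groups: int = 7
    #: per-modality timing jitter standard deviation, seconds
    jitter_sd_s: Mapping[str, float] = field(
        default_factory=lambda: {"audio": 0.35, "pianoroll": 0.12, "waveform": 0.15}
    )
    #: per-modality detection probability for levels 1..4 (monotone in level)
    salience_by_level: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "audio": (0.30, 0.45, 0.60, 0.80),
            "pianoroll": (0.55, 0.70, 0.85, 0.95),
            "waveform": (0.50, 0.65, 0.80, 0.90),
        }
    )
    #: constant time bias applied in the audio-only condition, seconds
    audio_only_shift_s: float = -0.6
    spurious_rate_per_min: float = 0.3
    #: inclusive level range for spurious boundaries (tentative, hence weak)
    spurious_levels: tuple[int, int] = (1, 2)
    level_confusion_prob: float = 0.1
    spammer_fraction: float = 0.05
    #: spammers place at least this many times the template count
    spammer_multiplier: int = 5
    duration_range_s: tuple[float, float] = (20.0, 120.0)
    boundaries_range: tuple[int, int] = (2, 10)
    rng_seed: int = 0

    @property
    def n_participants(self) -> int:
        return self.n_groups * self.participants_per_group

    def validate(self) -> None:
        if self.n_pieces <= 0 or self.participants_per_group <= 0 or self.n_groups <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0.0 <= self.spammer_fraction <= 1.0:
            raise ConfigurationError("spammer_fraction must lie in [0, 1]")
        if not 0.0 <= self.level_confusion_prob <= 1.0:
            raise ConfigurationError("level_confusion_prob must lie in [0, 1]")
        if self.spurious_rate_per_min < 0:
            raise ConfigurationError("spurious_rate_per_min must be nonnegative")
        for m in MODALITIES:
            if self.jitter_sd_s[m] < 0:
                raise ConfigurationError("jitter standard deviations must be nonnegative")
            probs = self.salience_by_level[m]
            if len(probs) != 4 or not all(0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError("salience_by_level needs four probabilities in [0,1]")
            if any(b < a for a, b in zip(probs, probs[1:])):
                raise ConfigurationError("salience must be nondecreasing in level")
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi:
            raise ConfigurationError("duration_range_s must be positive and ordered")
        lo_b, hi_b = self.boundaries_range
        if not 2 <= lo_b <= hi_b:
            raise ConfigurationError("boundaries_range must be ordered with at least 2")


def combined_salience(boundary: TrueBoundary, modalities: frozenset[str]) -> float:
    """Noisy-OR detection probability over the modalities present."""
    miss = 1.0
    for m in modalities:
        miss *= 1.0 - boundary.salience[m]
    return 1.0 - miss


def generate_templates(config: SimulationConfig) -> list[PieceTemplate]:
    """Draw piece templates: durations, boundary times, levels, saliences.

    Within a template, salience is a fixed nondecreasing function of the true
    level in every modality, so stronger boundaries are never harder to detect
    in any channel.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    lo_d, hi_d = config.duration_range_s
    lo_b, hi_b = config.boundaries_range
    templates = []
    for i in range(config.n_pieces):
        duration = float(rng.uniform(lo_d, hi_d))
        n_bounds = int(rng.integers(lo_b, hi_b + 1))
        # keep boundaries off the extreme edges and separated by >= 1 s
        times = np.sort(rng.uniform(0.05 * duration, 0.95 * duration, size=n_bounds))
        while np.any(np.diff(times) < 1.0):
            times = np.sort(rng.uniform(0.05 * duration, 0.95 * duration, size=n_bounds))
        levels = rng.integers(1, 5, size=n_bounds)
        bounds = tuple(
            TrueBoundary(
                time_s=float(t),
                true_level=int(lv),
                salience={m: config.salience_by_level[m][int(lv) - 1] for m in MODALITIES},
            )
            for t, lv in zip(times, levels)
        )
        templates.append(
            PieceTemplate(piece_id=f"piece{i:02d}", duration_s=duration, true_boundaries=bounds)
        )
    return templates


def assign_conditions(
    pieces: Sequence[PieceTemplate], config: SimulationConfig
) -> dict[int, dict[str, str]]:
    """Latin-square condition assignment: group index -> piece_id -> condition.

    Each piece is annotated under every condition by exactly one group, and
    each group's per-condition piece counts differ by at most one.
    """
    config.validate()
    if config.n_groups != len(CONDITIONS):
        raise DesignError(
            f"Latin-square design needs {len(CONDITIONS)} groups, got {config.n_groups}"
        )
    assignment: dict[int, dict[str, str]] = {g: {} for g in range(config.n_groups)}
    for j, piece in enumerate(pieces):
        for g in range(config.n_groups):
            assignment[g][piece.piece_id] = CONDITIONS[(g + j) % len(CONDITIONS)]
    return assignment


def planted_spammers(config: SimulationConfig) -> dict[str, int]:
    """Which participants are spammers and which single level each uses.

    Drawn from a seed stream dedicated to the spammer design, so the planted
    ground truth is recoverable from the config alone — which is what lets
    the outlier-filter tests check that exactly these (participant, level)
    pairs get caught.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    n_total = config.n_participants
    n_spammers = int(round(config.spammer_fraction * n_total))
    ids = sorted(rng.choice(n_total, size=n_spammers, replace=False).tolist())
    levels = rng.integers(1, 5, size=n_spammers)
    return {f"p{i:03d}": int(lv) for i, lv in zip(ids, levels)}


def _perturb_level(level: int, prob: float, rng: np.random.Generator) -> int:
    if prob > 0 and rng.random() < prob:
        level += int(rng.choice((-1, 1)))
    return int(min(max(level, LEVELS[0]), LEVELS[-1]))


def simulate_annotations(
    pieces: Sequence[PieceTemplate],
    assignment: Mapping[int, Mapping[str, str]],
    config: SimulationConfig,
) -> AnnotationDataset:
    """Simulate every participant's annotations under the assigned conditions."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    spammers = planted_spammers(config)

    annotations: list[Annotation] = []
    durations = {p.piece_id: round(p.duration_s, 3) for p in pieces}
    for g in range(config.n_groups):
        for s in range(config.participants_per_group):
            pidx = g * config.participants_per_group + s
            participant = f"p{pidx:03d}"
            is_spammer = participant in spammers
            spam_level = spammers.get(participant, 0)
            for piece in pieces:
                condition = assignment[g][piece.piece_id]
                if is_spammer:
                    times = _spam_times(piece, config, rng)
                    for t in times:
                        annotations.append(
                            Annotation(participant, piece.piece_id, condition,
                                       _clamp_time(t, durations[piece.piece_id]), spam_level)
                        )
                    continue
                modalities = condition_modalities(condition)
                jitter = max(config.jitter_sd_s[m] for m in modalities)
                shift = config.audio_only_shift_s if modalities == frozenset({"audio"}) else 0.0
                for b in piece.true_boundaries:
                    if rng.random() >= combined_salience(b, modalities):
                        continue
                    t = b.time_s + shift
                    if jitter > 0:
                        t += rng.normal(0.0, jitter)
                    level = _perturb_level(b.true_level, config.level_confusion_prob, rng)
                    annotations.append(
                        Annotation(participant, piece.piece_id, condition,
                                   _clamp_time(t, durations[piece.piece_id]), level)
                    )
                n_spurious = rng.poisson(config.spurious_rate_per_min * piece.duration_s / 60.0)
                for _ in range(n_spurious):
                    # accidental extra clicks are tentative: annotators who are
                    # unsure reach for the weak strength levels
                    annotations.append(
                        Annotation(
                            participant, piece.piece_id, condition,
                            _clamp_time(rng.uniform(0.0, piece.duration_s),
                                        durations[piece.piece_id]),
                            int(rng.integers(config.spurious_levels[0],
                                             config.spurious_levels[1] + 1)),
                        )
                    )

    annotations = _dedupe(annotations)
    return AnnotationDataset(
        annotations=sorted(annotations, key=Annotation.sort_key),
        pieces=durations,
        provenance=f"synthetic(seed={config.rng_seed})",
    )


def _spam_times(
    piece: PieceTemplate, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    n = config.spammer_multiplier * max(len(piece.true_boundaries), 1)
    n += int(rng.integers(0, 3))  # at least 5x the template count
    return rng.uniform(0.0, piece.duration_s, size=n)


def _clamp_time(t: float, duration: float) -> float:
    return round(float(min(max(t, 0.0), duration)), 3)


def _dedupe(annotations: list[Annotation]) -> list[Annotation]:
    # millisecond rounding can collide two draws; keep the first occurrence
    seen: set[tuple] = set()
    out = []
    for a in annotations:
        key = a.sort_key()
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


def simulate_study(config: SimulationConfig | None = None) -> AnnotationDataset:
    """Templates + Latin square + annotation simulation in one call."""
    config = config or SimulationConfig()
    templates = generate_templates(config)
    assignment = assign_conditions(templates, config)
    return simulate_annotations(templates, assignment, config)
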