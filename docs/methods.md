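# Methods

## Data model

A boundary annotation is a record (participant, piece, condition, time in
seconds, strength level 1–4).  Pieces carry a duration; conditions are the
seven tokens APW, AP, AW, PW, P, W, A naming the modalities available while
annotating (audio, piano roll, waveform).  Times are stored at millisecond
precision: sub-second placement differences are meaningful in performed
music, finer digits are interface noise.

## Outlier removal

For each strength level L, the number of boundaries each participant placed
at L (aggregated over all their pieces) forms a count distribution over all
participants present in the dataset, with zeros for participants who never
used L.  A participant whose count exceeds the upper outer fence
Q3 + 3·IQR loses all of their level-L boundaries; other levels are kept.
Quartiles use linear interpolation between order statistics (numpy's
default).  The fence is sensitive to this convention, so it is fixed rather
than configurable; the multiplier (3, the *outer* fence) is exposed for
sensitivity analysis only.  The decision unit is the participant/level pair,
not the piece: the failure modes this filter targets — annotators who use a
single level for everything, or who ignore the instructions — are properties
of the participant, and a per-piece fence on 8-annotator cells would be
statistically unstable.

## Condition pooling

The seven raw conditions pool into five grouped ones: AV ← {APW, AP, AW},
A ← {A}, V ← {PW}, P ← {P}, W ← {W}.  Pooling happens after outlier removal
and conserves every annotation exactly once; because the Latin square
assigns each condition of a piece to a different participant group, AV
concatenates three disjoint groups' data (24 annotators) rather than
duplicating anything.

## Boundary profiles

Annotations are binned on a uniform grid of width 0.1 s (half-open bins
[k·w, (k+1)·w); the final instant clamps into the last bin).  Each boundary
contributes its strength level (1–4) as mass, so the profile is a weighted
boundary function; the alternative 0.25–1.0 weighting used by the F-measure
is available as a configuration.  0.1 s is finer than annotator motor
precision while keeping a two-minute piece at ~1200 bins; because the
transport distances are computed on this grid, the bin width is part of the
configuration fingerprint recorded with every result table.

Gaussian KDE curves (fixed bandwidth 0.5 s, not data-adaptive, so curves are
comparable across conditions) serve visualization only and never enter any
distance.

## Transport distances

The 1-D optimal transport distance between profiles is the L1 gap between
their normalized cumulative sums, in bin units.  The unbalanced variant
destroys whole bins of mass at per-unit cost c = 2 by greedy descent:
each iteration evaluates every occupied bin on both sides (vectorized as a
rank-one update of the CDF), accepts the single removal that most decreases
`d_OT + c·(destroyed mass)` if the decrease is strict, and stops otherwise.
Normalizers are recomputed after every removal; destruction is charged on
raw (level-weighted) mass; a removal that would empty a side entirely is
never taken, since the normalized CDF is undefined at zero mass.  Ties
between equally good removals break toward the earlier bin, then toward the
first argument, making the computation deterministic.

Properties, measured rather than assumed (seeded instances, frozen into the
test suite): the greedy value never beats the exhaustive-subset optimum and
matched it on 500/500 random small instances; it is bounded above by d_OT,
nondecreasing in c, equal to d_OT at very large c, and value-symmetric under
argument swap on every instance tested (the greedy order is not provably
symmetric in general, hence the cross-piece distance matrix is symmetrized
explicitly).

Raw distances grow with the grid length, so every cross-piece quantity uses
the scaled distance raw/K, K the number of bins — a duration proxy on a
fixed-width grid.  The destruction cost is applied before scaling.

## Weighted F-measure

Per strength level, estimated and reference boundaries are matched
one-to-one, greedy nearest-first, within a hit window; per-level precision
and recall are combined as weighted means (weights 0.25/0.5/0.75/1.0 for
levels 1–4) over the levels present in either set — a level absent from both
sets does not dilute the mean, while a level present on only one side
contributes zeros, which is the metric's documented blind spot for
same-time/different-level agreement.  F_α = (1+α²)PR/(α²P+R) with α = 0.58
favours precision.  Degenerate conventions: two empty sets score perfect
agreement; an empty set against a nonempty one scores zero.

The default hit window is 0.5 s, the standard *fine* tolerance in
music-boundary evaluation.  The coarse 3 s window common for whole-piece
segment boundaries is available by configuration, but at this study's scale
— within-piece boundaries spaced around a second apart, pooled over many
annotators — a 3 s window lets every boundary match some counterpart, the
one-to-one matching saturates at the smaller set's size, and P/R collapse to
pool-size ratios (the AV pool has three times the annotators by design, so
its recall is capped near 1/3 regardless of structure).  At 0.5 s the score
responds to timing fidelity, which is the property of interest.

In the comparison tables the audio-bearing group (AV, or A in the unimodal
comparisons) is treated as the reference — it is the study's gold standard —
and the other group as the estimate.

## Study analysis

Seven comparisons per piece: (AV,V), (A,V), (AV,P), (A,P), (AV,W), (A,W),
(AV,A), numbered 1–7.  Each cell of the pieces × comparisons table is the
scaled uOT distance (or 1 − F_α) between the two pooled groups' profiles; an
empty side leaves the cell missing with a logged diagnostic, and such pieces
are excluded from rankings rather than imputed.  The global ranking sorts
comparisons by ascending median over pieces, ties broken by mean then by
comparison id.  Descriptive statistics run over all cells with the same
quartile convention as the fence.  Per-piece ranks use min-rank for ties;
the smallest/largest tallies attribute exactly one cell per piece, breaking
ties by the lower comparison id.

The MDS map embeds all (piece, group) profiles by classical (Torgerson)
scaling: square the symmetrized distance matrix, double-center, take the top
two eigenpairs; axis signs are fixed by making each axis's
largest-magnitude coordinate positive, so the embedding is deterministic;
Kruskal stress-1 is reported.  Profiles of different pieces live on grids of
different lengths, so each pair is compared on the union grid (the longer of
the two, zero-padded) and scaled by that grid's length, which reduces to the
ordinary scaled distance for same-piece pairs.  This pair rule is the
package's choice and is exposed through the configuration surface.

## Synthetic data generator

The generator emulates the study's design: 33 pieces with durations uniform
on [20 s, 120 s] and 2–10 "true" boundaries each (strictly increasing, ≥1 s
apart, levels uniform on 1–4); 7 groups × 8 participants; a cyclic Latin
square assigning each piece to every condition via exactly one group, with
per-group condition counts balanced to within one.

Noise model, per participant and piece:

* **Detection.**  Each true boundary is reported independently with
  probability 1 − Π(1 − s_m) over the modalities m present (noisy-OR — the
  simplest monotone rule in which an added modality never hurts detection).
  Per-modality salience is a fixed nondecreasing function of the true level;
  defaults make the visual channels more reliable than audio at every level
  (piano roll 0.55–0.95, waveform 0.50–0.90, audio 0.30–0.80), so audio-only
  annotators miss more of the visually salient structure.
* **Timing.**  Reported time = true time + Gaussian jitter with standard
  deviation equal to the largest jitter among present modalities (audio
  0.35 s, visuals 0.12–0.15 s), plus a constant −0.6 s bias in the
  audio-only condition, emulating the observed tendency of listeners to mark
  peaks earlier than readers of the visuals; times clamp to the piece.
* **Levels.**  The true level, perturbed ±1 with probability 0.1 and clamped
  to 1–4.
* **Spurious boundaries.**  A Poisson process at 0.3 per minute with uniform
  times and weak levels (1–2): accidental extra clicks are tentative.
* **Spammers.**  5% of participants use one level for everything and place
  at least five times the template's boundary count at uniform times — the
  behaviour the outlier fence is designed to catch.  The spammer design is
  drawn from a dedicated seed stream so the planted ground truth is
  recoverable from the config.

No quantitative noise magnitudes exist for human boundary annotators; these
values are stand-ins chosen once to look like plausible human behaviour
(timing error well under a second, detection strongly increasing in
boundary strength), with the modality asymmetry — faithful visuals,
jittered and shifted audio — as the scenario under study.  The −0.6 s
audio bias matches the scale of aurally shifted peaks reported for this kind
of material.  All draws come from a seeded generator; runs are
bit-reproducible.

What the generator does *not* emulate: real musical content (cadences,
dynamics), annotator-specific styles or learning over the session, zoom and
interface behaviour, correlated errors between participants, and hierarchical
or nested segmentation.  Passing end-to-end tests therefore show that the
pipeline recovers the modality structure *it simulates*, not that the same
effect sizes hold in real annotation data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full design scale (33
pieces, 56 participants) — a complete study analysis takes well under a
minute — with 20 replicates for the stability checks and 500 random
instances for the greedy-vs-exhaustive and metric-axiom property tests.
Greedy acceptance uses strict inequality with no epsilon; the number of
removals is bounded by the occupied bins, so termination is guaranteed.
Zero-mass profiles are rejected with a dedicated error rather than producing
NaNs; empty annotation sets produce all-zero profiles and are flagged at the
table level as missing cells.

## Known limitations

* The greedy destruction loop is a heuristic: optimality held on all small
  random instances tested, but no guarantee exists for larger supports.
* The scaled-distance units depend on the bin width, the level weighting
  and the cost convention; rankings are robust to these choices, absolute
  values are not, so tables record a configuration fingerprint.
* The F-measure table depends on the est/ref designation and the hit
  window; both are configurable and logged.
* Cross-piece MDS distances rely on the union-grid pair rule above; other
  rules (e.g. resampling to a common length) would give different maps.
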