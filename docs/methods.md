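# Methods

This note documents the models, conventions and numerical choices behind
`convoturn`, in the order the pipeline runs.

## Coordinate and unit conventions

All intervals are half-open `[start, end)` in seconds (float); floor-transfer
offsets (FTOs) are reported in milliseconds. Scheduled times are rounded to
the nearest sample at the working rate (48 kHz), and realised FTO metadata
stores the rounded values, so constant-scheme stimuli carry exactly the
requested offsets (190 ms and 50 ms are whole numbers of samples at 48 kHz).

## Voice activity detection

Per speaker track, the sample-level log-energy is `10·log10(x²)`, floored at
−120 dB so digital silence is well defined. The track is cut into 5 ms
windows; a window is speech when more than 15 % of its samples exceed the
track-wide **median** sample log-energy + 5 dB. Because the threshold is
relative to the median, the decision is invariant to a global gain change;
the rule presumes speech occupies less than half of each track's samples so
that the median sits on the noise floor — true for dyadic recordings where
each speaker holds the floor roughly half the time, and enforced by the
synthetic generator's silent lead/tail.

The published description of the detector leaves the framing ambiguous
(sample-level versus sub-frame energies); we evaluate per sample, which uses
every printed constant and is tested against an independent per-sample
oracle. Two smoothing durations are ours: interior silence runs shorter than
25 ms are filled, then speech runs shorter than 25 ms are dropped. Both are
far below the 300 ms pause threshold used downstream, so smoothing cannot
create or destroy linguistically relevant pauses; the final partial window
is evaluated over its available samples.

## Communicative states

Speech runs separated by at most `max_ipu_gap` (default 180 ms) merge into
inter-pausal units (IPUs). The published material distinguishes IPUs from
within-turn pauses but states no merge threshold; 180 ms keeps every
pause subject to the 300 ms rule intact while absorbing stop-gap silences.

Turns are sequences of connected IPUs of one speaker, including internal
pauses, bounded by floor transfers. The classification rule is the segment
logic of the turn-taking literature (gaps, pauses, overlaps-within,
overlaps-between): an IPU of the non-floor-holding speaker is an
**overlap-within** if and only if it lies entirely inside a single IPU of
the floor holder — the host vocalises throughout, so the interjection never
speaks alone. In every other case (the IPU starts in the host's silence,
outlasts the host's vocalisation, or bridges a host pause) there is a moment
of solo speech and the floor transfers. Consequences worth noting:

- an utterance that starts inside a host turn but ends after it is a floor
  transfer with negative FTO, not an overlap-within;
- speech uttered wholly inside a host *pause* takes the floor (two
  transfers), because the host is not vocalising around it;
- no duration constraint is placed on overlaps-within.

Simultaneous onsets (|Δ| < 1 ms) resolve to the speaker who continues
longer, then to track-label order — deterministic and vanishingly rare.
FTO_k = onset(turn_{k+1}) − offset(turn_k), in ms.

## FTO distributions

The logistic distribution models FTO collections; its location equals the
median, and the scale sets the spread. Fitting defaults to maximum
likelihood on the raw values (`scipy.stats.logistic.fit`); a
histogram-least-squares mode (50 ms bins) is provided for fidelity to
descriptions that fit "to the histogram", and the two agree within 5 % on
clean logistic data (tested). Sampling uses the explicit inverse CDF
`x = μ + σ·ln(u/(1−u))`. The NHQ→HIN transform is the affine map
`x' = to.μ + (to.σ/from.σ)(x − from.μ)`, under which the logistic family is
closed, so transformed NHQ draws are exact HIN draws.

The overlapping index η = ∫ min(f₁, f₂) dx is computed by adaptive
quadrature split at the density crossing points located on a 4097-point
grid over the union of the two μ ± 12σ spans; the integration error bound is
1e−4, and a Monte-Carlo estimator η = E_{f₁}[min(1, f₂/f₁)] serves as an
independent cross-check in the tests.

Two distinct "NHQ central values" coexist deliberately: the fitted location
μ = 139.8 ms and the constant 190 ms used by the conNHQ scheme (the
empirical corpus median). Both are exposed as named constants; the package
does not conflate them.

Quantiles (median, IQR) use linear interpolation (type-7), stated because
they feed the matched-subset selection.

## Manipulation and rendering

Per turn, in timeline order:

1. **Loudness equalisation** — one gain per turn scales the turn so the RMS
   over its IPU samples (pauses excluded) equals `target_rms` (default 0.05
   ≈ −26 dB FS; the published value is unnumbered, so it is configurable).
   Overlaps-within are equalised the same way with their own gain.
2. **Pause compression** — each internal pause longer than 300 ms is halved
   until shorter than 300 ms (1000 → 250, 600 → 150; exactly 300 ms is
   untouched). IPU audio is unchanged; later IPUs shift left.
3. **Overlap re-attachment** — overlaps-within keep their original offset
   relative to the (compressed) host turn start. If the compressed host can
   no longer contain one, its audio is still rendered but truncated 1 ms
   before the next turn's onset on collision; timeline metadata records the
   within-host extent only.
4. **Scheduling** — turn k+1 starts at turn k's offset plus the scheme's
   FTO: constants for conLow/conNHQ, i.i.d. NHQ draws, or NHQ draws pushed
   through the affine transform for HIN. A drawn FTO more negative than
   −0.9 × (previous turn duration) is redrawn (up to 10 times, then clamped)
   so an incoming turn cannot start before its predecessor effectively
   begins; the published procedure does not address this tail.

Rendering places each IPU's source audio (with 5 ms linear edge ramps
against clicks) at its scheduled position in a mono buffer after 200 ms of
leading silence; overlapping regions are summed, and only if the mix would
clip is one global gain applied (peak to 0.99) — per-region compression
would distort the loudness set in step 1. Silence between placements is
exact zeros. Per-speaker stems are kept alongside the mix so detection can
be re-run on rendered output.

Paired NHQ/HIN generation gives the NHQ segment raw draws and the HIN
segment the same sequence transformed, truncated or extended with fresh
draws to its own transfer count — with equal counts the HIN FTOs are the
elementwise affine image of the NHQ ones. Whether the original study matched
transfer counts between paired segments is unstated; this per-segment
re-sizing with a shared transform is our documented choice.

## Experiment lists

32 segments (4 pairs × 8) are assigned so each of the four schemes covers
exactly two segments of every pair; 10 lists are built, each with fresh
NHQ/HIN draw seeds (80 distinct NHQ renderings). Clock-based list selection
is replaced by explicit seed-indexed selection: every random element derives
from one master seed via `SeedSequence`-based child seeds tagged by role,
list, pair and segment. The VAS is coded 1–5 continuous with five anchor
points; the published rating differences imply some numeric coding that is
never stated, and the rank-based analyses are invariant to any strictly
monotone recoding.

## Synthetic data

The conversation generator emulates the stimulus-corpus segment statistics:
12–25 turn changes (uniform), lognormal speech duration per turn (median
1.5 s, log-SD 0.4, floored at 0.6 s), one internal pause in ~30 % of turns
(uniform 100–1200 ms, so some exceed 300 ms), overlaps-within in ~15 % of
turns placed inside the host's longest IPU with ≥ 300 ms clearance from the
turn edges, and original inter-turn gaps drawn from a logistic(200, 150)
clipped to [−100, 1500] ms. Surrogate speech is amplitude-modulated noise
(or a harmonic complex) at −20 dB FS over a −60 dB FS room-tone floor —
a ≥ 30 dB contrast comparable to a quiet recording booth. The emitted
timeline is exact, which is what makes the VAD → classifier → manipulator
loop testable to ground truth.

What the surrogate does **not** model: intelligible phonetic content,
prosodic turn-ending cues, level variation within and across talkers,
reverberation, crosstalk. Passing round trips therefore demonstrate the
timing pipeline, not robustness to real-world acoustics.

The rating generator is the linear model the analysis assumes: grand mean
3.2 on the 1–5 scale, per-scheme shifts (default ordering: constants ≥ NHQ
> HIN, HIN worst — chosen to mirror the qualitative pattern of interest,
not any published estimate), an optional slope on the stimulus's realised
FTO median, participant intercepts (SD 0.4), optional gender × scheme
shifts, residual SD 0.5, truncated to [1, 5]. Panel: 44 participants, 20
female / 24 male, one list per participant round-robin.

## Ratings analysis

Per participant, the repetitions of each scheme are averaged; cell means
enter a linear mixed model `value ~ scheme * gender` with a participant
random intercept, fitted by REML (statsmodels `MixedLM`). Fixed effects are
sum-to-zero coded so the joint Wald tests of each term are Type-III tests;
denominator degrees of freedom are containment-style (participant-level for
the between-subject gender term, observation-level for within-participant
terms) because statsmodels does not provide Satterthwaite df — the results
object states the method, and one test cross-checks fixed effects and F
statistics against R's lme4/lmerTest. Pairwise scheme contrasts are
estimated-marginal-mean differences averaged over gender, uncorrected by
default (a Holm option exists), with t, 95 % CI and p.

Rank-sum comparisons report the tie-corrected z; p-values use exact
enumeration of all group assignments for pooled n ≤ 12 and the
continuity-corrected normal approximation otherwise (measured agreement
with enumeration at n = 6+6: within ~0.016, which is why the tests assert
0.02). Degenerate input (all values identical) returns p = 1.

The matched-subset procedure formalises "extensive search" as a grid: a
window of fixed width (default 80 ms, the width of the published intervals)
slides in 5 ms steps over the matched parameter's range; windows qualify
when the rank-sum test on the matched parameter between NHQ and HIN records
has p > α and the group counts differ by at most 20; the window holding the
most records wins, ties going to the lower window. No multiple-testing
correction is applied inside the search, matching the published procedure.
Window width is fixed, not searched — varying it as well is a documented
open choice exposed as a parameter.

## Problem sizes and determinism

Round trips and rendering contracts run on 15-turn segments; distribution
round trips use 50 000 draws; calibration of the mixed-model stage uses 200
null replicates (type-I error lands within the binomial envelope of 5 %)
and 60 effect replicates at a HIN deficit of two residual SDs (power 100 %
observed). All stochastic operations take either an explicit seed or a
child seed derived from one master seed and role tags, so every reported
number is bit-reproducible.

## Known limitations

- The VAD presumes per-speaker tracks without crosstalk and a speech
  fraction below one half; it is not noise-robust and performs no
  diarisation or resampling.
- The classifier implements the two-speaker segment logic only; richer
  state inventories (e.g. mutual-overlap repair) are out of scope.
- Human-rating quantities (published F statistics, correlation
  coefficients, subset counts) depend on listener data that is not
  deposited; the analysis layer reproduces the machinery, and the synthetic
  generator only demonstrates parameter recovery on data built to its own
  assumptions.
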