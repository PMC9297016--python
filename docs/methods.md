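# Methods

## The model world

The generator produces a population of clans and individuals whose calls
are harmonic, frequency-modulated tones. Each signature parameter
(plateau frequency `f0_cf`, peak frequency `f0_max`, duration `dur`, CF
fraction) of an individual is

    base × (1 + clan offset + individual offset),

with offsets drawn i.i.d. normal at s.d. `clan_effect_scale` and
`individual_effect_scale`. Per call, parameters are the individual's
means times mean-one lognormal jitter with coefficient of variation
`within_individual_cv`; an optional bout-level shared jitter
(`bout_level_cv`) induces correlated within-bout variation. Defaults:

| parameter | default | why |
|---|---|---|
| `f0_cf_base` | 750 Hz | fundamental of a tonal mammalian long-distance call in the 0.6–0.9 kHz octave |
| `f0_max_base` | 1000 Hz | peak ~1/3 octave above the plateau |
| `dur_base` | 2.8 s | a long advertisement call |
| `cf_fraction_base` | 0.45 | long constant-frequency portion for A-type calls |
| harmonics | 6, 5–7 dB/step rolloff | audible stack without aliasing at 32 kHz |
| `individual_effect_scale` | 0.08 | 8% between-caller s.d.: strong but not trivially separable identity cues |
| `clan_effect_scale` | 0 | the default world has no group signature (a flag injects one for power tests) |
| `within_individual_cv` | 0.04 | per-call jitter well below the between-caller spread |
| bout length | uniform on [2, 34] | only the observed range is known, not the distribution |
| SNR | 15 dB | a clean field recording |

Whoop types follow a fixed template: an optional leading preliminary (P)
whoop (short: duration × 0.35), a body of asymmetric/symmetric (A/S)
whoops, and an optional trailing terminal (T) whoop (flat, lowered
frequency). Edge probabilities (0.5) and the A/S mix (50/50) are
assumptions — no quantitative type rates are available — and are config.
The contour template family is piecewise smooth: cosine-ramp onset (from
0.92 × plateau), flat plateau, cubic-smoothstep upsweep, cosine decay (to
0.75 × peak). Any family with CF-then-upsweep anatomy would do; this one
is differentiable and makes ground truth analytic. Subharmonics are
rendered at exactly half-integer multiples of f0 (no period-3 regimes),
as the simplest structure satisfying the detector's definition. The
amplitude envelope is a Tukey window with 1% cosine edges, chosen so that
the 99%-energy duration of a clean render stays within a few percent of
the declared duration.

Ground truth for the CF features is computed by applying the CF
definition to the analytic contour on a 1 ms grid, so generator truth and
extractor output are stated in the same terms.

**What the generator does not emulate:** propagation loss and
reverberation over km ranges, overlapping callers, non-stationary
savannah noise, vocal-tract filtering (formants), amplitude-contour
individuality, and realistic whoop-type base rates. Passing tests
therefore demonstrate that the pipeline recovers signatures *of the kind
injected* under additive white noise — not that real recordings carry
them.

## Feature extraction

All analysis runs at 32 kHz (polyphase resampling); entropy and CPP at
8 kHz. The 99%-energy window trims 0.5% of squared-sample energy from
each tail (symmetric-tail convention, standard for energy-criterion
durations). Ridge tracing uses 1024-sample hann windows, hop 256, FFT
zero-padded to 4096 (≈7.8 Hz bins), search band 0.2–2 kHz, frames more
than 35 dB below the loudest dropped, inter-frame jump capped at 20% of
the current f0, and parabolic sub-bin refinement. The tracker seeds at
the strongest frame whose unconstrained spectral peak lies near the
median per-frame peak: subharmonic episodes can be the loudest part of a
call, and an unguarded energy-max seed locks the contour an octave low.
Hand-traced contours, where available, are imported and resampled onto
the frame grid instead.

CF segmentation takes the longest contiguous frame run, ending no later
than the contour peak, inside ±10% of the median pre-peak contour
frequency; ties (run length, peak value) break to the earliest, and the
median is taken over retained (voiced) frames. A contour peaking at its
first frame has no CF portion (`dur.cf = 0`, flagged). The upsweep spans
CF end to the contour peak. Subharmonic detection compares summed
spectrogram energy in bands around k·f0 vs (k−½)·f0 (k = 1..6, half-width
0.2·f0); a frame is subharmonic-dominated only on strict inequality, and
dB ratios are floored/capped at ±60 dB so the feature stays finite for
the forest.

Spectral entropy follows the 4 ms block / 3.5 ms overlap geometry at
8 kHz: per block, a hann periodogram (17 bins); the block's spectrum
estimate is the Welch mean over the heavily-overlapped neighbouring
blocks within ±4 ms, and the normalized Shannon entropy −Σp log p / log N
is averaged over blocks inside the energy window. The Welch stage is an
estimator-quality choice: a single 32-sample periodogram has Dirichlet
sampling noise that caps white-noise entropy near 0.89, while the
smoothed estimate reaches ≈0.96 yet leaves stationary or slowly-modulated
tones (a whoop's FM drifts ≪ one bin over the span) at their leakage
floor ≈0.32. The floor is window-limited: 4 ms windows cannot localize a
tone below ~0.3 on this scale.

CPP uses the same blocks, FFT zero-padded ×2: real cepstrum of the dB
spectrum, a straight line regressed on quefrency over the range implied
by the 100–1200 Hz f0 band (clipped to the available quefrencies), CPP =
peak height above the line. It is scale-invariant (amplitude shifts the
whole log spectrum). Note a 4 ms block resolves periodicity only for
f0 ≥ ~500 Hz (two periods per block) — adequate for whoop fundamentals;
the block length is config for lower-pitched material.

## Signature testing

Splits are leakage-proof by construction and asserted at runtime: the
clan scheme holds out one uniformly chosen caller per clan (caller sets
disjoint between train and test), the individual scheme one uniformly
chosen bout per caller (bout sets disjoint; every caller present in
both). Entry requirement for the individual scheme: bouts with ≥3 calls,
then callers with ≥2 surviving bouts. Forests use 500 trees,
`max_leaf_nodes` = training-set size, per-split feature subsampling
(√p) and bootstrap resampling; vote fractions are fractions of trees
voting a class (majority semantics), not averaged leaf frequencies.
Rows are canonically ordered (by whoop id) before fitting so results are
invariant to input row and column order at fixed seeds; a single seed
fans out to per-repeat generators via `SeedSequence`.

WE is computed per repeat from the realized train/test compositions and
averaged — each split has its own chance level because callers differ in
call counts. A uniform-1/K mode exists behind a flag. Importance is
test-set permutation importance averaged over repeats (the mean-decrease-
in-accuracy estimator); a retrain-without-feature mode is available as a
cross-check. Failure-flagged feature rows are excluded before splitting,
with counts logged in the manifest.

## Redundancy

The prefix aggregate after k calls is the unweighted mean of the k
per-call vote vectors (equal to pooling tree votes, as tree counts are
equal); "probability correct" is the vote mass on the true caller (mean
posterior), with an argmax-accuracy variant reported alongside. The
analysis refuses to run unless mean single-call accuracy strictly exceeds
mean WE. The equal-informativeness baseline treats each call as an
independent symmetric categorical observation (correct w.p. p, each wrong
class (1−p)/(K−1)) and decides by plurality — the Bayesian MAP rule under
that likelihood — awarding 1/|tied set| on ties; the tie rule is chosen
because it makes exact enumeration auditable and yields the analytic
identity curve(2) = p. Exact mode enumerates integer partitions of the
wrong-vote counts (practical to k ≈ 15); Monte Carlo extends further.

## Problem sizes and numerical choices

The shipped analysis and the test suite run a 480-whoop world
(4 clans × 5 callers × 4 bouts × 6 calls, 15 dB SNR) with 100–200 CV
repeats, and 20-repeat importance runs — sizes at which every effect
tested is already decisive on one CPU. Degenerate inputs are errors, not
silent defaults: silent waveforms, empty search bands, single-class
training sets, single-caller clans, single-bout callers, empty quefrency
ranges. Tolerances asserted in tests: ≤2% median recovery error for
contour frequencies, ≤5% for durations (noiseless); baselines agree with
brute force to 1e-10 and with Monte Carlo within 3 s.e.

## Known limitations

The ridge tracker assumes one dominant tonal voice; crossing noises or
overlapping callers will corrupt contours (such rows surface as failures
or outliers, not crashes). The clan-scheme null distribution is
population-conditional: with few callers per clan, a finite population
can show accuracy a fraction of an s.d. away from WE without any
injected clan effect, which is why the no-signature check is stated in
units of the repeat s.d. Entropy and CPP at 4 ms blocks are coarse
single-number summaries; they discriminate phonation quality (noisiness,
subharmonics) but are not calibrated voice-quality measures.
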