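# Methods

## The question and the statistic

At the top of the primate ventral visual stream (inferotemporal cortex,
IT), image identity is usually described by the *direction* of the
population response vector. This package implements the complementary
analysis: whether the *magnitude* of the population response — the L2
norm √(Σᵢ rᵢ²) of the vector of per-unit spike counts rᵢ — predicts how
memorable an image is. Image memorability is a per-image score in
[0, 1] interpreted as a chance-corrected hit rate for recognizing the
image as previously seen: 0 maps to chance, 1 to ceiling.

The headline statistic is the Pearson correlation, across images,
between memorability and population response magnitude, with spike
counts taken in an 80 ms window 180–260 ms after stimulus onset.
Behavioral validity is assessed with the point-biserial correlation
between per-image memorability and the binary correct/incorrect
familiarity reports, computed on the raw (image, session) records.

## Synthetic recordings

Because magnitude estimation needs many hundreds of units and real
multi-session recordings are not bundled, the package ships a generator
whose defaults are the study conditions the pipeline targets: 27
sessions, Poisson-distributed population sizes with mean 26 units,
novel/familiar image pairs at n-back delays {1, 2, 4, 8, 16, 32, 64}
(the n-back is the number of intervening trials, exact by construction
of the trial schedule), and 600 ms trials binned at 20 ms from −200 to
+400 ms around stimulus onset.

Per-bin spike counts are Poisson at a rate that is flat at the unit's
baseline (uniform 2–10 spikes/s) before onset and through an 80 ms
latency, and from 80 ms onward becomes

    rate = baseline × evoked_gain × max(0, 1 + β·(m − m̄)) × L
           × (1 − s  on familiar presentations),

where

- `evoked_gain` (default 2) makes a unit visually responsive; a
  configurable fraction of units (default 0.88, matching the screened
  fraction in the reference study) carries it, the rest stay at
  baseline and should be removed by screening;
- β (`magnitude_coupling`, default 0.2) couples the population gain to
  the image's memorability m (uniform on [0, 1] unless supplied), with
  m̄ the distribution mean. β = 0.2 makes slot magnitudes span roughly
  20% across the memorability range, the regime the analysis operates
  in;
- L (`image_gain_sd`, lognormal, default σ = 0.25) is an image-specific
  content gain: image-driven response variation unrelated to
  memorability. σ was chosen together with β so that the full pipeline
  at default conditions recovers a slot-level correlation near the
  regime the method is designed to detect (r ≈ 0.65 across seeds);
- s (`suppression_fraction`, default 0.06) is repetition suppression of
  the familiar presentation.

Binary familiarity reports are correct with probability
0.5 + m·(ceiling − 0.5) (ceiling default 1.0). All randomness flows
through named substreams of a single seed (one stream per session and
purpose), so regenerating behavior never shifts spike counts, and
identical configs are bit-identical.

What the generator does *not* emulate: unit-to-unit tuning/selectivity
structure (population direction is unstructured noise here),
autocorrelated slow drifts, burstiness or non-Poisson count dispersion,
eye movements, and any image content beyond a scalar gain. Passing
tests therefore demonstrate that the *pipeline* recovers what it is
supposed to recover under its stated noise model — not that real IT
data behave this way.

## Screening

Units: paired two-sided t-test across trials on spike counts in
−200–0 ms vs 80–280 ms; pass at p < 0.01. The protocol the study
states does not say whether the test was paired; pairing (each trial
contributes both windows) is the natural reading and is used
throughout. Zero-variance differences make the statistic undefined;
such units are reported as failing with p = NaN and flagged.

Sessions fail on the first violated criterion, in order: (1) stability —
max/min of the grand mean rate over four equal contiguous trial blocks
must be < 2 (the source criterion names no block structure; quarters
are this package's operationalization); (2) responsiveness — more than
50% of units must be visually responsive, operationalized as the same
evoked t-test at α = 0.05 (a reproducible proxy for raster inspection,
flagged as such); (3) completed novel/familiar pairs must *exceed* 100
(strict, per the criterion's wording). Loosening α can only turn
failing units into passing ones (monotone by construction).

## Pseudopopulation construction

Within each n-back level, the image count is set by the session with
the fewest completed pairs at that level. Each other session is
subselected to that count by keeping its lowest- and highest-scoring
images and filling the remaining slots with the images whose scores are
nearest to values evenly spaced between the two extremes — assignment
is greedy from the lowest spacing target upward, without replacement,
with ties broken by score then image id (the source procedure names no
assignment rule; this one is deterministic). Retained images are ranked
by memorability; rank-matched images across sessions share a slot.
Slot memorability is the mean of contributing scores (their SD is
reported per slot); each unit's slot response is its analysis-window
count averaged over the image's novel and familiar presentations, so
`response = (novel + familiar) / 2` holds exactly, and both addends are
retained for split analyses and repetition suppression. Unit columns
concatenate across sessions; permuting session order only permutes
columns.

Content-subset controls (e.g. excluding images with faces/body parts,
a configurable 19% of generated images) rebuild the pseudopopulation
from scratch on the unflagged subset rather than dropping slots.

## Statistics

- Pearson and point-biserial p-values use the t transform with n − 2
  degrees of freedom. The point-biserial statistic is computed by the
  closed-form mean-difference formula, which equals Pearson on a 0/1
  encoding (asserted to machine precision in the tests).
- Repetition suppression is population-level by default:
  1 − grand-mean(familiar)/grand-mean(novel). A per-unit mean-of-ratios
  variant exists but is not the default.
- Window sweeps slide an 80 ms (configurable) window across the trial
  in bin-aligned steps; zero-variance windows yield missing r with a
  warning, not an exception, and no multiple-testing correction is
  applied across windows.
- The "proportional magnitude spread" reported in summaries is
  max/min slot magnitude − 1 — this package's own definition, since the
  quantity has no canonical one.
- The high-rate-unit control drops the ceil(f·N) units with the highest
  mean rate; f defaults to 0.05.

## Network analysis

Per layer, the response magnitude of an image is the L2 norm of the
full post-nonlinearity output vector of that layer. Per-layer Pearson
correlations with memorability get percentile-bootstrap 95% CIs
(resample image indices with replacement, recompute r; 10,000
replicates by default; CI endpoints are the empirical 2.5/97.5
centiles; BCa is deliberately not used). Resampling is independent per
layer and per condition. The one-sided condition comparison reports the
rate at which the second condition's replicate r meets or exceeds the
first's, pairing replicates by index; ties count toward the numerator
(conservative) and the reported p is floored at 1/replicates, the
bootstrap's resolution. Because conditions resample independently, two
identical datasets under different streams give p ≈ 0.5; two literally
identical replicate arrays give p = 1 under the tie rule.

Real networks (e.g. AlexNet-family models with published weights)
connect through the forward-pass contract — any object exposing
`layer_names` and `forward(x)` returning each hidden layer's
post-nonlinearity output vector in hierarchy order. The bundled
`ToyFeedforwardNet` (three conv-like stages + two fully connected
layers, fan-in-scaled random weights) exists to exercise that contract
and the oracle tests; it is not meant to reproduce any published
per-layer correlation values, which would require the original image
set and trained weights.

## Image preprocessing and score calibration

Images are resized to 256×256 with bilinear interpolation (Pillow's
half-pixel-center convention, stated so fixtures are bit-exact), the
per-channel mean RGB intensity is subtracted (a scalar triple, not a
mean image), and ten 227×227 crops are taken: center, four corners,
and each flipped about the vertical axis, in that fixed order. The
mean over crops is order-invariant; the order only matters for
serialized fixtures. Mirroring the input swaps left/right corner crops
with their flipped partners exactly; the center crop shifts by one
pixel because the 29-pixel margin is odd.

Raw per-crop network predictions are averaged and calibrated with the
clipped linear transform

    score = min(max((output − mean_pred)·2 + additive_mean, 0), 1),

with mean_pred = 0.7626 and additive_mean = 0.65 as defaults, so a
prediction at the calibration mean scores exactly 0.65 and the output
is always in [0, 1], monotone in the mean raw prediction.

The delay correction treats memorability as log-linear in retention
delay: m(t) = m(T) + α·ln(t/T), with α the decay factor (negative for
forgetting) and T the reference delay. The logarithm base is not
specified by the source description; the natural log is used and α
rescales under any other base. The stated inverse
(`correct_to_reference`) makes the round trip exact for any t > 0.
The equation's symbol for base memorability is inconsistent in the
source text (a symbol is named that never appears in the printed
equation); this implementation treats the reference-delay score as the
base memorability.

## Problem sizes and numerical choices

Default analysis sizes were chosen so the whole test suite and the
analysis scripts run in a few minutes on one core: 27 sessions ×
~26 units × ~130 pairs for the pipeline checks (the pooled
pseudopopulation lands at ~650 units × ~125 slots), 100-replicate
grids for null-coverage checks, and 1,000–10,000 bootstrap replicates
depending on the context. Windows must tile the trial period exactly
(half-open bins); misaligned windows are an error rather than being
silently rounded. Degenerate inputs (zero-variance magnitudes or
scores, single-class outcomes, empty vectors) raise errors in scalar
operations and yield flagged missing values inside sweeps and
bootstrap profiles, where one bad window or layer should not abort the
run.

## Known limitations

- The generator's coupling is a scalar gain; it cannot express
  direction-coded memorability or mixed selectivity, so it cannot
  falsify the magnitude hypothesis — it only tests recovery.
- n-back labels are not recoverable from the flat source-data layout;
  slots read from such tables carry a −1 sentinel and n-back-resolved
  analyses require session-level inputs.
- The session-stability and responsiveness criteria are deterministic
  proxies for judgments that were partly manual in the original
  protocol.
- Per-layer correlation magnitudes from the toy network are arbitrary;
  only the machinery (norms, bootstrap, one-sided comparison) is
  meaningful there.
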