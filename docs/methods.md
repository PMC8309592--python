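# Methods

This note documents the models, conventions and design choices behind
`vdep-eeg`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not establish.

## Data model

Recordings follow the pre-processed DEAP dialect: one array per
participant of shape `n_trials × 40 channels × 8064 samples` at
fs = 128 Hz.  Each 63-s trial consists of a 3-s pre-trial baseline
followed by 60 annotated video seconds; channels 1–32 are EEG in the
Geneva ordering of the Biosemi-32 cap, channels 33–40 are peripheral
signals that the analysis drops.  Upstream artefact handling
(down-sampling, EOG removal, 4–45 Hz band-pass, re-referencing) is
assumed already applied and is not modelled.

Annotations are per-second labels from two independent experts for each
of four visual design elements/principles (VDEPs): colour (cold/warm),
balance (asymmetrical/symmetrical), movement (fast/slow), light
(bright/dark), each either class 1, class 2 or *unclear*.  The four
VDEPs are processed fully independently.

## Synthetic-data generator

The generator exists so that every stage can be tested against known
ground truth; it emulates the data's geometry and the statistical
structure the pipeline exploits, not EEG biophysics.

**Latent truth.**  Per video, second and VDEP a latent class in {1, 2}.
Classes arrive in alternating runs with Geometric(1/`mean_run_s`)
lengths (default mean 5 s), so interval construction is non-trivial.
Runs shorter than 2 s are legitimately consumed by trimming.

**Signal.**  One channel-second is

    x(t) = n(t) + Σ_b A_b sin(2π f_b t + φ_b)

- `n(t)`: pink noise with power ∝ 1/f^β (default β = 1, per-sample SD
  `noise_std` = 1), generated in **independent half-second blocks**
  aligned with the half-second epoch grid.  With per-second blocks,
  adjacent epochs shared parts of a noise block and their band powers
  were weakly *negatively* correlated (lag-1 autocorrelation ≈ −0.12
  for θ), which deflated the null rejection rate of the rank-sum
  comparison; half-second blocks make epoch band powers exactly
  independent, as the test assumes.
- Tones: one per band at the band's geometric-centre frequency rounded
  to the nearest integer Hz — 2, 6, 10, 20, 37 Hz — hence bin-aligned
  for 1-s windows at 128 Hz.  The phase `φ_b` is drawn once per
  (participant, trial, channel, band) and kept coherent across the
  trial.  Coherence matters: with a fresh phase every second, the
  half-second epoch grid puts a phase discontinuity mid-epoch and the
  resulting spectral leakage smears an injected alpha effect into
  neighbouring bands (observed as spurious θ/β significance).  With
  coherent integer-Hz tones every extracted epoch contains pure
  in-band tones and the analytic prediction `P_b = A_b²/2` per channel
  is exact.
- Amplitudes: `A_b = base_amplitudes[b] × Π_v gain(class_v, b)`, the
  product running over the VDEPs listed in `gain_vdeps` (default: all
  four).  Restricting `gain_vdeps` to one VDEP isolates a clean
  single-factor effect — with a 2× class-1 alpha gain the class-1/
  class-2 alpha power ratio is 4 up to the (additive) noise floor.
  The default gain map is a modest 1.5× class-1 alpha amplitude; the
  null is an empty gain map.
- The 3-s baseline and the `n_trials − n_videos` untagged filler
  trials carry base amplitudes only (no class effect); filler trials
  also verify that extraction skips trials without annotations.
  Peripheral channels are white noise — present only so the
  channel-drop step has something to drop.

**Annotators.**  Each expert independently reports *unclear* with
probability `annot_unclear` (default 0.05), otherwise the true class
with probability `annot_agreement` (default 0.9) and the wrong class
otherwise.  The keep probability after two-expert resolution is
`(1−u)²(a² + (1−a)²)` and is verified empirically.  The defaults are
package choices — real inter-expert agreement for this kind of tagging
is not publicly documented — and are surfaced in `SimConfig`, not
hard-coded.

**What passing tests do not show.**  The generator's oscillations are
stationary single tones, its noise has no artefacts, volume conduction,
or inter-channel correlation, and its class effects are global
amplitude scalings.  Success here validates the *pipeline arithmetic
and statistics*, not the claim that real EEG carries such effects;
conclusions about real recordings require the real data.

## Annotation resolution and balancing

A second is kept iff both experts gave the same non-*unclear* label;
discards are retained with a reason (*unclear* if **either** expert was
unsure — the strictest reading — else *disagreement*), and the
class-count summary reports both reasons separately plus their sum.
Balancing sub-samples the larger class uniformly without replacement
down to `n_v`, the smaller class size.  By default balancing is applied
to **epoch-yielding seconds** (those surviving trimming) rather than
raw tagged seconds, so the final epoch sets are exactly balanced at
`n_participants × n_v` per class; `balance_stage: tags` restores
tag-level balancing for fidelity with tag-level count tables.

## Epoch extraction

Seconds are 0-based; sample ranges are half-open.  Tagged second `s`
of a trial occupies samples `[(s+3)·128, (s+4)·128)`.  Per class
interval `[s0, s1)` the first and last 0.5 s (64 samples) are trimmed
and the remainder cut into contiguous non-overlapping 1-s windows:
epoch k covers video time `[s0+0.5+k, s0+1.5+k)` and is attributed to
second `s0+k`, giving ⌊L−1⌋ epochs per participant.  Epochs never
overlap the baseline and never cross interval boundaries.  No
perception-time lag is applied.

Min-max normalization maps an epoch to [0, 1] using the minimum and
maximum of the **whole 128 × 32 matrix** (a per-channel variant is
available); a constant epoch maps to zeros with a logged warning.
Normalization feeds the decoder only — band-power statistics consume
raw amplitudes, since power on a per-epoch-rescaled signal would mix
amplitude information across channels and epochs.

## Spectral analysis

Band filtering zeroes all DFT coefficients with frequency outside
`[lo, hi)`; DC and Nyquist are always zeroed; a bin belongs to the band
iff `lo ≤ f < hi`.  Default edges: δ 1–4, θ 4–8, α 8–13, β 13–30,
γ 30–45 Hz (conventional ranges truncated at the upstream 45 Hz
low-pass; δ content in such data is residual — it is computed
regardless and should be interpreted with that caveat).  "Mean band
power" is the time-average of the squared band-filtered signal —
computed equivalently via Parseval as `2/N² Σ_{k∈band} |X_k|²` — then
averaged unweighted over the 32 EEG channels.  A rectified-amplitude
variant (mean |x_b(t)|) is available as an option.

## Statistics

Normality screening uses the Kolmogorov–Smirnov test with the
Lilliefors correction (parameters estimated from the sample; table
p-values via statsmodels; n ≥ 5 and non-constant required).  Class
comparisons use the two-sided Mann–Whitney U with midrank ties: exact
p by full enumeration when `n1+n2 ≤ 12` and no ties, otherwise the
normal approximation with tie and continuity corrections.  α defaults
to 0.05 and no multiple-testing correction is applied by default (the
per-band, per-VDEP tests are reported individually); a Holm-adjusted
column is always present and `holm: true` bases the significance flag
on it.  Epochs are treated as independent observations — participants'
epochs are pooled, with no mixed-effects structure.  This is a known
limitation: in real data epochs from one participant are correlated
and the pooled test is anti-conservative in that respect.

## Decoder

**Channel layout.**  The storage order of the source data lists the
left hemisphere front-to-back and then the right, so adjacent matrix
columns are often distant on the scalp.  The default re-ordering is a
greedy nearest-neighbour walk over the 2-D montage coordinates
(Biosemi-32 standard montage via mne) starting at Fp1, refined by
2-opt.  Mean adjacent scalp distance: 0.031 m versus 0.038 m for the
storage order — a serpentine row-by-row scan was also evaluated and
rejected because its row-to-row hops make it *worse* (0.044 m) than
the storage order.

**Architecture.**  `conv_filters` 3×3 same-padding convolution blocks
(ReLU, 2×2 max-pool) — default (16, 32) — a 64-unit dense ReLU layer
and one sigmoid output; binary cross-entropy, Adam (lr 10⁻³), batch
64, ≤ 30 passes with early stopping on validation loss (patience 3,
best weights restored).  The network centres its [0, 1] inputs to
[−0.5, 0.5] at the input layer (a fixed transform; it roughly halves
the passes needed to converge).  The implementation is a compact
NumPy one (im2col GEMM convolutions, float32 throughout) and is
deterministic given the seed.

**Validation.**  Non-exhaustive k-fold cross-validation: k independent
stratified random 90/10 train/validation splits (Monte-Carlo CV, not a
partition), one freshly initialised model per split; ROC-AUC, accuracy
at threshold 0.5, and PR-AUC (average-precision step integration) per
fold plus means.  Splits are at the epoch level by default, so epochs
from the same participant and video can appear on both sides — this
mirrors the pooled-epoch design and inflates absolute performance; a
`group_split` option (by participant or video) provides leakage-free
splitting as the rigorous alternative.

## Problem sizes used in validation

The shipped tests run the pipeline at reduced scale, chosen to keep
every check statistically meaningful: generator contract tests use
2–4 participants and 3–4 videos (500+ epochs where power ratios are
asserted); the null calibration of the band comparison uses 1000
independent single-participant, two-video replicates (~45 epochs per
class each); decoder recovery uses 12 participants × 4 videos
(≥ 2000 epochs) with a (8, 16)-filter network, learning rate 2×10⁻³
and ≤ 5 passes — ample for the planted 2× alpha effect, and the same
configuration stays at chance (AUC ≈ 0.5) on null data.  The
arithmetic and oracle checks (enumeration, periodogram, pair
counting) are exact at any scale.

## Numerical conventions and edge cases

- Determinism: every stochastic step derives its generator from an
  explicit seed (`numpy` `SeedSequence` substreams per stage); reports
  carry a configuration hash excluding output paths, and wall-clock
  timings are excluded from the report hash.
- Degenerate inputs: constant epochs normalize to zeros with a
  warning; constant samples are rejected by the normality test; empty
  classes abort balancing and comparison with explicit errors;
  intervals referencing missing trials are skipped with a warning;
  intervals shorter than 2 s yield zero epochs without error.
- Max-pool gradients are routed by value equality; exact up to ties,
  and ties at zero are inert because the preceding ReLU zeroes those
  gradients.

## Known limitations

- Pooled-epoch statistics and epoch-level CV splits ignore the
  participant hierarchy (see above); group-wise splitting is provided
  but not the default, to keep the default faithful to the pooled
  design.
- The generator's effects are band-amplitude scalings; decoders
  exploiting richer structure (phase, cross-channel patterns) are not
  exercised by it.
- The Lilliefors p-values come from the standard table approximation,
  which saturates at its tabulated extremes.
- Real tagged-video EEG data is access-restricted; nothing in this
  package's validation substitutes for it.
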