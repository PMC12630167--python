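# Methods

`holopollen` is a desk-scale re-creation of an operational automatic
pollen monitoring stack: an airflow cytometer detects single aerosol
particles and records, per event, two greyscale hologram
reconstructions plus a 13-channel induced-fluorescence spectrum; a
neural classifier assigns a taxon (or abstains); classified events are
aggregated into concentration time series and judged against a manual
Hirst-type reference trap with season-aware statistics. Everything
here runs on synthetic data from a fully parametric generator, so every
quantity the evaluation produces has a known ground truth.

## Synthetic event generator

**Hologram appearance model.** A rendered event is a particle
silhouette over a noisy background: a disc of the sampled diameter,
with `spike_count` Gaussian boundary protrusions (pores/spikes, height
14% of the radius), a lens-like interior brightness profile, and a
multiplicative band-limited surface texture of relative amplitude
`texture_amplitude` (correlation length 1.5 px). The second hologram
re-renders the same particle with an independent sub-pixel centre
jitter and fresh background noise, emulating the instrument's two
reconstruction planes. This is a *classifiable proxy*, not a physical
reconstruction: it deliberately preserves the one morphological
contrast that matters operationally — water droplets are perfectly
smooth (`texture_amplitude = 0`, no protrusions) while pollen grains
carry surface texture — and nothing else about holographic image
formation. The frame side length is configurable (operational default
200 px at 1 µm/px; the test suite uses 32–64 px at 2–4 µm/px, which
keeps the same contrasts at a fraction of the compute).

**Taxon profiles.** Default profiles cover the main Swiss allergenic
taxa (Poaceae, Betula, Alnus, Corylus, Fraxinus, Quercus, Fagus) plus
water droplets, with grain diameters drawn from the usual
palynological ranges (normal, truncated to the stated support).
Two structural choices are load-bearing:

- *Grass is smooth.* Poaceae grains are rendered smooth and round
  (texture 0.12, one pore), which is exactly why fog droplets
  (10–100 µm, smooth, non-fluorescent) are morphologically confusable
  with them.
- *The Betulaceae triplet is holography-ambiguous by construction.*
  Betula, Alnus and Corylus share identical diameter, texture and
  protrusion parameters but carry disjoint fluorescence spectra
  (pairwise mean distance ≫ the channel spreads). Holography alone
  cannot split them; fluorescence can. This gives the fluorescence
  branch measurable value in the paired-model experiments.

**Fluorescence.** The 13 channels are treated as anonymous: each taxon
has per-channel means and spreads, sampled as zero-truncated normals.
Droplets have near-zero means (water does not fluoresce). With
probability `fluor_missing_prob` an event carries no fluorescence at
all (not every device has the module; weak signals fall below the
noise threshold); the droplet default is 0.6, pollen taxa 0.1.

**Arrival process.** Campaigns are hourly Poisson streams following
per-taxon daily rate curves; fog episodes inject droplet-class events
only inside their intervals. Daily concentration relates to the
arrival rate through the instrument sampling flow
(concentration = events / (flow × hours); flow default 2.4 m³/h,
configurable — any mis-specification is absorbed by the scaling
factor).

**Manual trap emulation.** The reference series is
`efficiency × true` with negative-binomial-like counting noise on an
equivalent sampled volume (gamma multiplier of unit mean and variance
`noise_dispersion` modulating a Poisson count on `sample_volume` m³ per
day). `noise_dispersion = 0` is the exact noiseless limit, used by the
recovery tests.

## Classifier

A two-branch network, trained from scratch (never from pre-trained
weights):

- **Hologram branch:** VGG-style 3×3 convolution blocks with ReLU and
  2×2 max pooling over the two stacked hologram planes, flattened into
  32 image features. Operational default: three blocks of two
  convolutions (16/32/64 channels) at 200 px. The desk-scale
  configuration used throughout the tests is three single-convolution
  blocks (8/16/32) at 64 px, or two blocks at 32 px — the widths are
  ordinary configuration, chosen to keep a full training run under a
  minute on one CPU.
- **Fluorescence branch:** a single dense layer of 8 units (few
  neurons on purpose — the spectra are low-dimensional and a wide
  branch over-fits them) over the 13 channels plus a presence flag.
- **Fusion:** concatenation into a linear softmax head.

**Missing modality.** Absent fluorescence is encoded as a zero vector
with presence flag 0 — identically at training, prediction and in the
exported graph (a tested bit-for-bit contract). During every training
epoch a fraction `fluor_mask_prob` (default 20%) of the fluorescence
signals is discarded at random; the mask is re-drawn per epoch rather
than fixed per dataset, which is the stronger augmentation reading of
the discard rule. This keeps the image branch trained even when
fluorescence is informative, so the model degrades gracefully instead
of collapsing when the modality is missing.

**Confidence and abstention.** Confidence is the maximum softmax
probability. At threshold c an event is labelled with the argmax class
iff confidence ≥ c and the argmax is unique; ties abstain
(conservative). Abstention is therefore monotone: the classified set
at a higher threshold is a subset of the set at a lower one.

**Fluorescence-blind baseline.** The paired experiments compare a
normally trained model against one trained with `fluor_mask_prob = 1`
(fluorescence never seen). At prediction time the blind model is also
fed fluorescence-masked events: its fluorescence weights received no
gradient signal, so feeding them real spectra would inject
initialisation noise unrelated to the scientific question (what the
modality contributes).

**Implementation and determinism.** The network is a small numpy layer
library with manual backprop (im2col convolutions, Adam, float32),
verified against central-difference gradients at 1e-6. All randomness
flows from explicit seeds; a fixed seed reproduces training
bit-for-bit on one CPU. Batched and single-event prediction agree to
1e-6 (single-precision kernels may reorder reductions).

**Export.** Models serialise to ONNX (opset 13; Conv / Relu / MaxPool /
Flatten / Gemm / Concat / Softmax, float32 initializers, class list in
the model metadata), written and parsed directly at the protobuf wire
level, with a numpy graph executor for inference from the file. The
round-trip reproduces native logits within 1e-5 (measured: exact).

## Prefilter

A deterministic morphological filter runs before the network: Otsu
thresholding of the first hologram, largest connected component,
equivalent diameter (µm), solidity and eccentricity. Defaults accept
diameter 5–150 µm, solidity ≥ 0.8, eccentricity ≤ 0.95; rejections
carry a reason code (`empty`, `size`, `solidity`, `eccentricity`).
The thresholds are this package's own defaults.

## Evaluation statistics

All metrics are computed on **daily** series (the season rule is
daily; hourly aggregation is kept for display and conservation checks).

- **Kendall's tau-b** between paired manual and automatic daily
  values, tie-corrected (zero-concentration ties dominate pollen
  series). Computed via `scipy.stats.kendalltau`; the test suite holds
  an independent O(n²) pair-enumeration oracle. A completely tied
  vector yields the undefined-metric sentinel.
- **Scaling factor S** = Σ manual / Σ automatic over the common period
  (ratio of sums, robust to zero days; lower is better automatic
  sampling). Undefined when the automatic total is zero.
- **Off-season noise ratio R** = mean automatic concentration on
  off-season days / mean on in-season days.
- **Out-of-season rule:** a day is off-season iff it lies in *any*
  sliding window of W = 7 consecutive days in which at least k = 4
  days have manual concentration below T = 20 particles/m³. The
  any-window (member) semantics — rather than labelling window starts —
  is deliberate and is what the brute-force oracle enumerates. A
  consequence worth knowing: at a sharp off→in transition the first
  W − k = 3 season days are absorbed into the off-season. The
  parameter-recovery test therefore defines its "planted" R by
  applying the same rule to the generator's expected (noise-free)
  series, so only sampling noise separates planted from measured.
- **Threshold sweep and envelope:** the three metrics as functions of
  the confidence threshold; undefined values propagate as explicit
  sentinels (never silently dropped — envelopes report per-point
  contributing-site counts). Cross-site envelopes are pointwise
  mean/min/max.

## Experiment sizes and what the tests show

The validation campaigns are sized for a single CPU: paired-model
comparisons run 5 seeds of 6-epoch trainings at 32 px (~240 training
events each); the separable 4-class recovery uses 600 train / 200 test
events at 64 px and 10 epochs; the noiseless recovery campaign is 40
days of arrivals evaluated without rendering. The fog campaign places
its three fog episodes deep inside a 7-day off-season block (ahead of
a 10-day season) precisely so the R contrast between the paired models
is driven by droplet false positives rather than by the window-rule
boundary absorption described above.

Passing these tests shows the pipeline's internal consistency and that
the fluorescence branch carries real signal *under the generator's
assumptions*. Real monitoring data differ in ways the generator does
not emulate: holographic fringes and reconstruction artefacts,
correlated multi-day weather, aggregates and debris beyond what the
prefilter bounds describe, device-to-device variability, and
fluorescence spectra that overlap far more than the synthetic
profiles. Results here bound what the code does, not how well the
approach works in the field.

## Numerical choices and degenerate inputs

- Undefined metrics are NaN sentinels with explicit `is_defined`
  semantics; every consumer handles them (envelopes count contributing
  sites; sweeps record sentinels in place).
- Tau on series shorter than 2, seasons without off-days, zero
  automatic totals, and empty event streams all take defined error or
  sentinel paths (tested).
- Otsu thresholding on a near-constant frame returns an empty-frame
  sentinel which the prefilter turns into a `reject(empty)`.
- Adam (lr 3e-3, β = 0.9/0.999) with batch size 32; He
  initialisation; cross-entropy loss. Images are fed in [0, 1] without
  further normalisation; fluorescence intensities are O(1) by
  construction.

## Known limitations

- The hologram model contains no diffraction physics; a model trained
  on it will not transfer to real holograms.
- The 13 fluorescence channels are anonymous; no excitation/emission
  structure is modelled.
- The ONNX writer emits exactly the operator set this architecture
  needs; arbitrary graphs are out of scope (the parser rejects unknown
  operators by name).
- Events always carry exactly two holograms; single-hologram devices
  are not represented.
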