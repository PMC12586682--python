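# Methods

## Melt-curve model

A real HRM instrument reports dye fluorescence while temperature ramps from
60 to 90 °C at 0.1 °C/s; the simulator reproduces that grid (301 points at
0.1 °C). Each amplicon is decomposed into `n_domains` contiguous segments of
near-equal length (default 3; remainder distributed left-to-right). Domain
melting temperature follows the classical salt-adjusted GC rule

    Tm_d = 81.5 + 16.6 log10([Na+]) + 0.41 (%GC_d) − 675 / L_d

with [Na⁺] = 0.05 M. Overall helicity is a length-weighted mixture of
two-state logistic transitions,

    θ(T) = Σ_d w_d · σ((Tm_d − T) / s),

with transition width s = 0.9 °C, and fluorescence interpolates between a
double-strand baseline (2600 − 9·(T−60) RFU) and a single-strand baseline
(350 − 1.5·(T−60) RFU), scaled by a per-run amplitude factor
(lognormal-ish: N(1, 0.05), floored at 0.05) and shifted by a per-run Tm
offset N(0, 0.15 °C), plus i.i.d. N(0, 6 RFU) noise. This is deliberately a
*phenomenological* model — multi-domain logistic mixing, not
nearest-neighbor partition functions. The goal is sequence-sensitive,
controllable, bit-reproducible signatures: a single G/C↔A/T substitution
moves one domain's Tm by 0.41·(100/L_d) ≈ 0.55 °C, which is the kind of
small-but-nonzero separation that makes congeneric species pairs hard in the
field.

What the generator does **not** emulate: heteroduplexes and mixtures,
instrument optics and well-to-well calibration drift, plate-edge effects,
sequence-order effects within a domain (only composition matters here), and
real intraspecific haplotype variation. Passing tests therefore demonstrate
that the *pipeline* recovers sequence-determined signatures under controlled
noise — not that the classifier ships field-ready for real instrument
exports, which should be revalidated with the CSV column-mapping adapter.

Amplification is geometric growth with efficiency 0.95 capped at a plateau,
mapped linearly to fluorescence such that the noiseless plateau-minus-baseline
signal equals `plateau_nfu` exactly (the scale is solved from the copy-number
trajectory, avoiding a float mismatch at the 8-NFU decision boundary; the
LOI comparison additionally carries a 1e-9 guard so an exactly-at-threshold
signal passes while 7.9 NFU still fails).

Weak (sub-LOI) reactions are assigned deterministically by run index —
exactly ⌊n·weak_fraction⌋ runs, spread evenly — so tests can assert exact
exclusion counts. The end-to-end corpus uses weak_fraction = 0.165,
mirroring the observed field rate of reactions that fail to reach the limit
of identification.

## Curve representations

* **Melt curve**: −dF/dT via Savitzky–Golay (window 2.1 °C ≈ 21 points,
  cubic, `mode="interp"` so edges use polynomial fits and output length
  equals input length).
* **Normalized HRM**: lines are fitted to the pre-melt (61–65 °C) and
  post-melt (86–89 °C) windows; signal is expressed as percent of the
  distance between the lines. The two-line method makes the output invariant
  under any added linear ramp. Window positions are an assumption — the
  instrument software's exact convention is not public — and are
  configurable. Note a genuine edge case: when a domain's transition tail
  reaches into a window (domain Tm ≳ 81 °C vs the 86 °C post window), the
  fitted baseline tilts slightly and the noiseless normalized curve can
  undershoot 0 by up to ~0.1 % of scale. Amplicons whose transitions sit
  clear of the windows stay within [−0.01, 100.01].
* **Derivative HRM**: −d(normalized)/dT, same smoothing convention.
* **Difference plot**: pointwise sample − reference on the shared grid.
* **LOI**: mean of the last 3 amplification cycles minus mean of cycles 1–5;
  pass iff ≥ 8 NFU (strict below-threshold failure).

## Rendering

224×224 RGB PNGs at fixed per-kind axis limits computed **once from the
training split** (pooled min/max padded 5 %), so absolute peak position is a
stable visual feature and no test-set information leaks through scaling.
Curves are drawn as 3 px black lines; axes and ticks are kept but no legend
or label text is drawn (label text would leak class identity into pixels).
Encoding goes through Pillow with fixed settings and no timestamp metadata,
giving byte-identical PNGs for identical inputs.

## Classifier

The default backbone is a 3-block CNN (3×3 conv → ReLU → 2×2 max-pool;
channels 8/16/32) on 64×64 grayscale downsamples of the PNGs, followed by a
*flattened* final feature map projected to a 64-unit latent layer and a
softmax head. Flattening (rather than global average pooling) is deliberate:
the discriminative signal is *where* along the temperature axis the peaks
sit, and pooling spatial structure away measurably slowed learning within the
fixed 20-epoch budget. Forward and backward passes are explicit numpy
(im2col convolutions), which makes training exactly reproducible under a
fixed seed and exposes the feature-map gradients Grad-CAM needs.
Optimization is AdamW (decoupled weight decay, applied to weights only);
the default search grid is lr ∈ {1e-3, 1e-4} × wd ∈ {0, 1e-4}, batch size 8.
Deeper pretrained backbones (`resnet18`, `resnet50`, `vit`) are registered
as optional plug-ins that require torch/torchvision at run time.

Protocol: species with fewer than 5 retained runs are excluded; the rest are
split 60/20/20 per species by largest-remainder rounding with val and test
guaranteed ≥ 1 (a 5-run class splits 3/1/1). Splitting operates on run ids so
the three image kinds of one reaction never straddle splits. Grid search
trains one 20-epoch cycle per cell and scores each by its *optimal validation
accuracy* (the best epoch's validation accuracy); ties break toward lower
learning rate, then lower weight decay, for determinism. The winner is
retrained on train+val for 20 epochs and evaluated once on the untouched test
split. Metrics are support-weighted (weighted recall is algebraically equal
to accuracy; macro averaging is available via scikit-learn directly);
confidence is the maximum softmax probability, averaged over **all** test
predictions (not only correct ones — an assumption, flagged here).

Fusion trains three independent per-kind networks, freezes them, concatenates
their 64-d latents (192-d) and fits only a linear softmax head.

## Open-set rule

A prediction whose confidence is **strictly below** the threshold is flagged
"untested species"; equality counts as tested. The sweep merges the seen test
split with all unseen-species predictions and, treating "untested" as the
positive class (both orientations are exported in the CSV), reports
precision/recall/F1 at each threshold (default grid 0.5–1.0 in 0.05 steps;
0/0 ratios are defined as 0).

## Synthetic panel

`fixtures.make_panel` builds n species of 223 bp amplicons as
primer + core + primer-site. Cores are built from exact-GC-count segments
(domain GC targets ~0.50–0.72, keeping every domain Tm inside ~70–81 °C,
clear of the normalization windows), and rejection sampling guarantees every
non-designated species differs from all others by at least 3 G/C counts
across the three domains — distinct species must have distinct melt
signatures. Three designated pairs are the exceptions and the point: species
1/2 differ by exactly 4 nucleotides, 3/4 by 12, and 2/5 by a single
nucleotide (all substitutions flip the GC class so each one shifts a domain
Tm). These mirror the hardest congeneric cases the assay faces. All fixture
sequences are synthetic stand-ins constructed by code, not records of real
organisms.

## Scale choices and determinism

The end-to-end study runs 30 species × 12 replicates (16.5 % weak), holds 5
species out as unseen, and trains on melting-curve images with the 2×2 grid —
sizes chosen so the whole protocol completes in a few minutes on one CPU
while keeping ≥ 5 post-filter runs per species and a ~50-sample test split.
Every stochastic draw flows from one seeded generator per run
(`SeedSequence((params_seed, replicate_seed))`), recorded in run metadata;
simulation, rendering, manifests, training and prediction are all
bit-reproducible given the same seeds.

## Known limitations

* The melt model ignores sequence order within a domain; two amplicons with
  identical domain compositions are indistinguishable by construction.
* Single-nucleotide pairs sit near the classifier's resolution limit
  (≈ 0.55 °C domain shift vs 0.15 °C replicate jitter); occasional
  cross-calls within such pairs are expected and mirror field behavior.
* The LOI plateau convention (last-3 minus first-5 cycles) is one reasonable
  operationalization of a normalized-fluorescence threshold; instruments may
  compute NFUs differently.
* Confidence thresholding is the only open-set mechanism; no calibration
  (temperature scaling) or distance-based scores.
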