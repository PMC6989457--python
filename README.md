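# eccnet

An eccentricity-dependent neural network (ENN) model of foveated vision,
with a matched single-resolution CNN control and a one-shot same/different
evaluation protocol, implemented in pure scientific Python (NumPy forward
and backward passes — no deep-learning framework required).

The ENN samples a simulated visual field with 10 centered crops whose
spans grow exponentially by a factor of 1.5 from a 0.5-degree foveal crop
(~19 degrees total at 450 px/degree).  All crops are resampled to a common
grid and processed by one shared 4-layer conv/pool stack; the per-channel
feature vectors are element-wise max-pooled across scale channels.  The
architecture is scale-tolerant by construction and degrades with
eccentricity the way peripheral vision does: a stimulus far from fixation
is seen only by the coarse channels.

One-shot evaluation stores features from a single target presentation and
compares them to a test presentation (same glyph or a paired, structurally
similar distractor) by Pearson correlation, with an accuracy-maximizing
threshold per condition and d-prime reporting.  Two similarity rules are
provided: the symmetric rule (pooled vs pooled) and the asymmetric rule
(the stored per-channel template bank vs the scale-pooled test feature),
which reproduces the central/peripheral learning asymmetry.

## Layout

- `eccnet.stimuli` — field calibration, procedural stroke-based glyph
  generation (training classes and novel target/distractor pairs),
  rendering at given size (arcmin) and eccentricity (degrees), PNG/JSON
  I/O, and an IDX (MNIST-format) reader.
- `eccnet.pyramid` — the multi-scale centered-crop sampler.
- `eccnet.nnops` / `eccnet.networks` — NumPy conv/pool/backprop layers,
  the ENN and CNN models, training (Adam, cross-entropy), checkpoints.
- `eccnet.oneshot` — similarity metrics, optimal thresholds, d-prime,
  condition runner, invariance windows.
- `eccnet.experiments` / `eccnet.cli` — config-driven scale- and
  translation-invariance experiments at desk scale.

## CLI

```sh
eccnet train -c config.yaml -o results/ --seed 1      # train ENN + CNN
eccnet scale-exp -c config.yaml -o results/           # size-change accuracy table
eccnet translate-exp -c config.yaml -o results/       # invariance windows + heatmaps
eccnet report -o results/                             # summarize CSVs
```

Without `-c` a desk-scale default profile is used (reduced sampling
density and filter counts; identical geometry).  All outputs embed the
config hash and seed.

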