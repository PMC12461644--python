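# Methods

`medi2i` implements prompt-conditioned multi-domain medical image-to-image
(I2I) translation: a single generator renders an input slice into any
appearance domain described by a natural-language "medical prompt", with the
prompt embedded by a contrastively pre-trained dual encoder.  This note
records the model, the defaults and why, what the synthetic study does and
does not show, and the numerical choices made where the design was open.

## Medical prompts

A scan's metadata (DICOM tags and curated keywords) is rendered through a
fixed sentence template: a domain sentence ("A T2-weighted magnetic
resonance imaging of the brain for the subject."), then optional sentences
for contrast agent, scanner hardware, scanning sequences, sequence variants,
scan options, acquisition parameters, preprocessing, and viewing plane.
Sentences whose keywords are absent are omitted.  Sentences that strongly
determine image appearance — the domain sentence, contrast, preprocessing —
are flagged *essential*; scanner and parameter sentences are optional.
The multi-timepoint ordinal ("first", "second", ...) is rendered inside the
domain sentence ("A first DCE magnetic resonance imaging ..."), since it
modifies the acquisition named there.

Training-time augmentation drops each optional sentence independently with
probability `drop_prob` (default 0.5; not dictated by the protocol, chosen
as the maximum-entropy midpoint) and shuffles the survivors.  A candidate
prompt *matches* an image when every candidate sentence occurs in the
image's original prompt and every essential sentence of the original occurs
in the candidate.  Sentence identity is exact string equality after
whitespace normalization: templated sentences are canonical strings, so
fuzzy matching would only blur the label matrix.  The rule is deliberately
asymmetric (dropping an optional sentence keeps a match; adding a foreign
sentence breaks it).

## Dual encoders (contrastive pre-training)

The text encoder is a CLIP-style causal transformer (full scale: 12 layers,
width 768, 12 heads, byte-pair vocabulary of 49,152, context 256); the
activation at the end-of-sequence token is layer-normalized and linearly
projected into the domain-encoding space.  The image encoder is a ConvNeXt
backbone (full scale: 7x7 stride-1 stem with 96 channels; stages of
96/192/384/768 channels, 3/3/9/3 blocks, strides 4/2/2/2) whose global
average pooling is replaced by a single multi-head QKV attention-pooling
layer whose query is conditioned on the average-pooled feature map (8 heads;
no positional embedding is added to the pooled tokens, so pooling is
permutation-invariant — adequate because domain appearance is a global
property).  Both embeddings are L2-normalized; the projection width is 512
at full scale (CLIP convention; the width is not dictated by the
architecture).

Pre-training minimizes a supervised multi-positive contrastive loss with
temperature tau = 0.07.  For batch label matrix M (text x image, built by
the prompt-matching rule under augmentation), every matched pair contributes
a -log softmax term in both the text-to-image and image-to-text directions,
averaged over the matches of its row or column; rows/columns without
matches contribute zero (a guard — each image always matches its own
augmented prompt).  Whether the projections are normalized before the dot
products is not forced by the loss definition; we normalize, consistent with
cosine-similarity retrieval at inference.

The tokenizer is a lower-cased BPE trained deterministically (ties in merge
counts broken lexicographically) from a lexicon of template sentences; the
shipped vocabulary has ~150 tokens, sufficient because prompts are
templated.  A full-scale vocabulary trained on free text can be loaded
through the same class.

## Translation triad

* **Structure encoder**: 7x7 stride-1 stem (96 channels), then two stages
  (192 and 384 channels, 1 and 3 ConvNeXt blocks, stride 2 each) with a
  single-head pre-norm self-attention block between consecutive blocks.
  Output: anatomical features at 1/4 resolution, 384 channels.
* **Conditional decoder**: mirrors the encoder; stride-2 convolutions become
  2x nearest upsampling + stride-1 convolution; the output passes through a
  LeakyReLU (slope 0.01; the slope is not architecture-determined, 0.01 is
  the common default).  Every convolution inside decoder blocks is a
  **hyper-convolution**: its kernels are `W0 + sum_r c_r(T) B_r`, where the
  coefficients `c(T)` come from a two-layer perceptron on the domain
  encoding T and `B_r` is a learned basis (rank 8 full scale, 4 tiny).  This
  grouped low-rank factorization keeps the hyper-network's parameter count
  bounded while letting T re-colour the decoder; zeroing the perceptron
  provably reduces the decoder to an unconditional network, which the test
  suite uses as a weight-routing oracle.  The conditioning notation
  G(Phi || T) is realized exclusively through these generated kernels, not
  by channel concatenation.
* **Discriminator**: three kernel-4 stride-2 convolutions (96/192/384
  channels), conditional (hyper-convolutional) blocks interleaved with
  self-attention, and a 1x1 single-channel head scoring patches at 1/8
  resolution.  Least-squares GAN targets are used: D minimizes
  (D(real)-1)^2 + D(fake)^2, G minimizes (D(fake)-1)^2.  Normalization
  layers in D are omitted (LayerNorm inside the conditional blocks only).

## Losses

With lambda_L1 = 10, lambda_p = 0.1, lambda_con = 1, lambda_adv = 5,
lambda_cos = 0.1, tau = 0.07:

* Reconstruction (paired, both directions): L1 plus a perceptual term.  All
  pixel reductions are means, so the printed weights are stable across
  image sizes.
* Structure consistency: MSE between the paired feature maps (raw features)
  plus a symmetric per-pixel InfoNCE on channel-normalized features over
  the common foreground mask, max-pool downsampled by 4 (a block is
  foreground if any of its pixels is — stride-4 features aggregate the
  whole block).  The InfoNCE uses raw sums in its canonical form; inside
  training it is averaged per masked pixel and evaluated on at most
  `pcl_max_pixels` (64) randomly chosen foreground pixels, so its weight
  does not grow with foreground area and memory stays bounded.
* Triangular consistency (cross-dataset): L1 + perceptual between
  G(E(G(E(x_src)||T_int))||T_tgt) and x_tgt, with x_int drawn from another
  dataset of the same organ within the mini-batch (uniform over the other
  datasets, then uniform over their domains).
* Adversarial (least-squares, conditioned on T_int) and a cosine semantic
  loss between the frozen image encoder's embedding of the generated
  intermediate image and T_int.
* Stage totals: init = rec + lambda_con*con;
  fine = rec + lambda_con*con + tri + lambda_adv*adv + lambda_cos*cos.

The perceptual extractor is pluggable.  The default is a deterministic
fixed-seed two-layer convolutional projection (identity + two random conv
scales, frozen at construction): it behaves like a small frozen backbone,
requires no download, and makes every result reproducible bit-for-bit.  A
pre-trained VGG/AlexNet extractor can be passed in where available; all
formulas are agnostic to the backbone.

The generator's adversarial gradient is propagated through the structure
encoder as well as the decoder (configurable), following the joint
optimization over both.

## Preprocessing

Intensity normalization: N(X) = (max(X, Rmin) - Rmin) / RX with Rmin = 0
(MRI) or -1024 (CT and CBCT); RX = the volume's 99.5th percentile (MRI,
computed over all voxels including background — configurable), 3000 (CT),
1500 (CBCT).  No upper clipping: MRI values in the 0.5% tail pass through
above 1, and the PSNR convention R = 1 nominally assumes [0, 1].
Resampling targets 1x1x1 mm for brain and breast and 2.5x1x1 mm for abdomen
and pelvis (trilinear).  Volumes are padded (zeros) or randomly cropped to
a cube; 2D slices are drawn in a uniformly random axial/coronal/sagittal
plane; paired volumes of one subject reuse the same offsets, plane, and
index.  Deterministic evaluation uses center placement and the center
slice.

## Metrics

PSNR = 10 log10(R^2/MSE) with R = 1 (identical inputs are reported as
infinite explicitly); SSIM with a uniform 7x7 window, population moments,
c1 = 1e-4 and c2 = 9e-4 (unit intensity range), averaged over windows fully
inside the image; a layer-summed perceptual distance with the pluggable
backbone; Dice (two empty masks define 1); ASSD over 8-connectivity
contour pixels with exact Euclidean distance transforms in physical units;
AUC by the rank-statistic formula with mid-ranks for ties (the closed form
presumes unique ranks; mid-ranks make it equal the pair-counting
probability, which the tests verify).  Slice-wise MSE with volume averaging
is used when volumes are compared.

## Synthetic study

The generator emulates the statistical structure the training procedure
assumes: multiple "datasets", each with paired (spatially aligned) domains;
distinct subjects across datasets sharing an organ; prompt attributes
mapping one-to-one onto appearance operators.  A subject is a smooth random
3D anatomy of nested shells (rim, subcutaneous-fat-like ring, parenchyma)
plus a focal lesion, stored as a label map shared by all domains.
Operators: per-class intensity lookup per pulse sequence (T1/T2/FLAIR
tables), lesion enhancement x1.4 for contrast, fat suppression x0.15,
rim zeroing for skull-removal, Gaussian smoothing (sigma 0.7 px), additive
Gaussian noise (sigma 0.02, foreground only, clipped to [0, 1]).  Fat
suppression and contrast act on disjoint tissue classes, so attribute
combinations commute and a held-out combination (default: fat-saturated T2)
is renderable without appearing in training — the zero-shot fixture.

Default layout: dataset "alpha" = {T1, T2}, dataset "beta" = {T1fs, FLAIR},
10 subjects each, 64^3 label maps, split 3:1:1 by subject.  Intensity
tables were chosen so that domains are well separated (identity-baseline
PSNR between domains roughly 10-21 dB) while the additive noise keeps the
attainable ceiling near 34 dB.

What passing tests show: the pipeline learns prompt-image alignment,
renders prompt-controlled appearance, transfers across datasets through the
triangular loss, and generalizes to a held-out attribute combination.
What they do not show: robustness to real MRI physics (bias fields, partial
volume, motion), anatomical variability beyond smooth blobs, or full-scale
(256^2, 27,950-scan) behaviour.

## Desk-scale study conditions

All neural components run on a pure-NumPy reverse-mode autodiff substrate
(`medi2i.nn`) written for this package: no GPU framework is required.
Dense convolutions use im2col + BLAS; stride-1 convolutions with large
kernels dispatch to an exact FFT path; every primitive is verified against
central finite differences.

The full-scale configuration (architectures above; batch 60 for 50 epochs
for pre-training, batch 6 with 5 init + 45 fine epochs at AdamW lr 1e-4 for
translation, 256^2 slices) is retained for conformance checks.  The desk
study uses reduced "tiny" configurations as first-class citizens: text
width 64 / 2 layers / projection 64; image stages (16, 32, 64, 128); the
translation triad at one-eighth channels with one block per stage
(hyper-rank 8, as at full scale); 64^2 slices.  Contrastive pre-training
runs 16 epochs at batch 60 over ~384 training slices, AdamW lr 3e-4 (the
optimizer for pre-training is not dictated by the translation recipe; the
larger rate suits the short contrastive schedule), keeping the state with
the best validation zero-shot accuracy.  Two-stage translation training
runs 4 init + 10 fine epochs of 24 steps (batch 6) at lr 1e-3 with cosine
annealing to 1e-4 — the schedule is roughly two orders of magnitude shorter
than full scale, and the learning rate is raised and annealed accordingly;
with the printed flat 1e-4 the shortened schedule visibly undertrains.
In the fine stage the intermediate domains of the chosen other dataset are
traversed (both of them, in the default two-dataset layout), so every
cross-dataset domain supplies collaborative supervision each step; the
discriminator takes one update per generator step on the mean of the
traversed adversarial terms (updating it once per intermediate
destabilized the short schedule).  Checkpoint selection maximizes mean
validation PSNR over center slices (ties to the latest epoch); a uniform
weight average over the top-k validation checkpoints is available as an
alternative smoother.

## Numerical choices and degenerate inputs

* Temperatures and loss weights as printed above; tolerances in oracle
  tests are 1e-6 (1e-4 for the SSIM reference comparison).
* Empty contrastive masks contribute zero; empty match-matrix rows/columns
  contribute zero; two empty masks give Dice 1; ASSD on an empty mask is an
  error; AUC requires both classes; zero vectors are rejected by the cosine
  loss; MSE = 0 reports infinite PSNR explicitly.
* Argmax ties (zero-shot classification) resolve to the lowest index;
  model-selection ties resolve to the latest epoch.
* Per-epoch RNG streams are derived from (seed, epoch), so resuming from a
  checkpoint reproduces the continuation exactly; all randomness flows
  through explicit `numpy.random.Generator` objects.

## Known limitations

2D slices only (no volumetric decoding); fixed training resolution; the
perceptual default is not a learned human-perception proxy, so its absolute
values are not comparable to published LPIPS numbers; the shipped
vocabulary covers templated prompts, not free text; the synthetic anatomy
is deliberately simple; adversarial training at desk scale is short, so the
discriminator mostly regularizes rather than sharpens.
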