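# Methods

This note records the model, the conventions, and the design choices made
where the protocol left room, in the order the pipeline runs.

## Label encoding

The three per-finding tables (abnormal / ACL / meniscus; two columns, exam
id and 0/1, optional `exam,label` header) are merged into one triple per
exam; an id missing from any table is an error, as is a non-binary value.
Only the five observed combinations are encodable — (0,0,0)→0, (1,0,0)→1,
(1,0,1)→2, (1,1,0)→3, (1,1,1)→4. A triple with a tear but no abnormality
flag is **rejected**, not mapped: inventing a sixth class would silently
change the label space. Exam ids are opaque strings throughout, so
zero-padded numerals survive round-trips.

## Slice standardization

Raw stacks have 17–61 slices; the model input has a fixed depth
(`target_depth`, default **15**). Output slice `j` sits at fractional
position `p_j = j·(D−1)/(T−1)`. Integer positions copy the original slice;
interior positions blend **0.2 × preceding + 0.8 × subsequent** slice.
Two readings of the procedure were possible — 15 slices total versus 15
new slices interleaved with originals — and we standardize to **15 total**,
which is what "a constant number of slices" requires. The fixed 0.2/0.8
weights are deliberately position-independent (they are not classical
linear-interpolation weights); we apply the stated rule literally rather
than guessing a position-dependent variant. Consequences tested: endpoint
slices are preserved verbatim, and outputs are convex combinations bounded
by the input extrema.

## Normalization and augmentation

Intensities are min-max scaled to [0, 1] **per volume** (the normalization
granularity was unstated; per-volume is scanner-agnostic and
shift/scale-invariant); a constant volume maps to all zeros. The grayscale
channel is replicated to 3.

Training augmentation: resize to `out_size` (default 224), 50% horizontal
and vertical flips, rotation drawn uniformly from ±45°, and a random
affine (scale 0.9–1.1, translation up to 10% of the frame, extra rotation
±10°). One random draw is made **per exam** and applied identically to all
slices — per-slice draws would decorrelate anatomy along the stack.
Resampling is bilinear with zero padding; rotation and affine compose into
a single warp so each slice is interpolated once. Evaluation applies only
the resize. All draws come from an explicit generator, making augmentation
bit-reproducible under a seed.

## Backbones

Because the training loop must be self-contained, the networks are written
on numpy: 3-D convolution via im2col/GEMM, batch normalization, ReLU,
2×2×2 max pooling (singleton dimensions left unpooled), global average
pooling, a linear head, and residual blocks, each with an analytic
backward pass; the test suite checks every layer's gradients end-to-end
against central finite differences in float64.

- `tiny3d` (the desk-scale default): three conv-pool blocks (8, 16, 32
  channels, the first convolution striding 1×2×2), global average pool,
  linear head to `embed_dim` (default 64).
- `resnet3d-10/18/34/50`: standard residual architectures (basic blocks
  1-1-1-1 / 2-2-2-2 / 3-4-6-3, bottleneck 3-4-6-3) with a 7³ stride-2
  stem. Builders accept an external weight archive by matching
  names/shapes; no downloader is included.

Initialization is He-normal from a seeded generator, so equal seeds give
bit-identical networks.

## Episodes and the prototypical head

`sample_episode` draws `n_way` classes without replacement (among classes
holding at least `k_shot + n_query` exams), then disjoint support and
query exams within each class. Episode labels are re-indexed 0..n_way−1 in
ascending global-class order, with the mapping recorded, so losses are
n_way-dimensional regardless of which class subset is in play.

Prototypes are per-class arithmetic means of support embeddings. Logits
are **negative squared** Euclidean distances (the standard prototypical
choice; plain distances give identical argmin predictions and only a
different softmax temperature, and no temperature is specified). Distance
ties break toward the lowest episode class id. The loss is the mean query
cross-entropy; its gradient flows through prototypes and queries into the
backbone.

## Training schedule

SGD with momentum 0.9; weight decay 5e-4 is added to the gradient
(classical L2 convention), so zero learning rate freezes the weights
exactly. One episode = one optimizer step. The MultiStep schedule —
initial lr 0.01, ×0.1 at task milestones 120 and 160 — is read literally
as a **globally counted per-task** schedule (a per-epoch reading is
available behind `milestones_per_epoch`). Stage 1 runs 3-way 5-shot
training tasks with 2-way 8-shot validation; the epoch count was never
fixed externally, so it is a config default (10; 2 in the desk-scale
experiments). Validation accuracy is the mean over validation episodes of
per-episode query accuracy, and the checkpoint with the highest validation
accuracy — the untrained initialization included — is kept.

Fine-tuning (stage 2) restarts the same loop from a checkpoint on classes
disjoint from the training classes (overlap is a protocol error unless
explicitly allowed), with 2-way 5-shot validation. The stage is specified
3-way even where only two unseen classes exist; we **clamp** `n_way` to the
available class count and log the clamp.

"2-way 8-shot" is taken to mean 8 *support* exams per class; the query
count per episode class is nowhere fixed and defaults to 10
(configurable).

## Federated protocol

Two (or more) clients receive disjoint, class-stratified shards
(remainders dealt round-robin from a random offset). All clients start
from one server-side initialization — averaging independently initialized
networks is meaningless under permutation symmetry. One round is: local
stage-1 training per client; upload of each client's best-validation
weights; size-weighted averaging `W = Σ nᵢWᵢ / Σ nᵢ` (with the equal
two-way split this equals the unweighted mean); redistribution; local
stage-2 fine-tuning. Which model is evaluated afterwards was left open;
both rules are implemented — a second aggregation of the fine-tuned
weights (default) or the best-validation client model — and the report
records which was used. `rounds` defaults to 1, matching the single
train→average→fine-tune pass described; multi-round FedAvg is available.
Clients are simulated in-process with seeds derived from (seed,
client id); the client API returns only weight mappings and scalar
metrics, and a test audits that no exam data is reachable from the
server-side result.

## Evaluation and metrics

Testing samples 2-way 8-shot episodes from the held-out classes and pools
all query predictions, mapped back to global class ids, into one confusion
matrix (rows = true). Accuracy is trace/total; precision, recall and F1
are one-vs-rest per class and **macro-averaged** — macro is the convention
uniquely consistent with recomputing the published example cells from
their confusion counts (micro averaging gives 0.8525, not 0.853, for the
axial precision). A class never predicted gets precision 0 with a warning.
Reported values round to three decimals (accuracy to one decimal in
percent) half-away-from-zero; half-way cells under a different rounding
convention are not asserted. For 2-way episodes the softmax probability of
the **larger** global class id (an arbitrary but recorded choice) is
scored per query, and ROC-AUC is computed by the rank/midrank method
(scikit-learn); AUC is undefined on single-class inputs.

## Synthetic generator

The generator emulates the *structural* features the pipeline depends on:
MRNet directory layout, variable depth (uniform on [17, 61]), per-plane
stacks, the five valid triples, and an imbalanced mixture (defaults
0.20/0.34/0.18/0.08/0.20 — class 1 largest and class 3 smallest, matching
the qualitative shape of the real class histogram, whose exact counts are
not published). Class signal is additive 3-D Gaussian blobs at fixed
fractional positions with class-specific sites, widths and amplitudes,
plus i.i.d. Gaussian noise (`signal_strength` 5.0, `noise_sd` 1.0 by
default — a signal-to-noise ratio of 5). Classes 3 and 4 share both blob
sites and differ only in the second blob's amplitude (×1.3), a contrast
that per-volume min-max normalization largely removes — so the (3, 4)
pair is hard by construction while pairs containing class 0 (pure noise)
are easy, mirroring the observed hardness ordering of class splits.

What passing tests on this generator do **not** show: robustness to real
anatomy, scanner variation, slice-thickness effects, or label noise. No
anatomical realism is attempted.

## Desk-scale experiment sizes

The end-to-end experiments (`fedproto.experiments`) use: 48×48 source
images resized to 32×32, depth standardized to 15, `tiny3d` with 64-d
embeddings, 2 epochs × 50 training tasks (3-way 5-shot, 5 queries per
class), 10 validation tasks per epoch (2-way 8-shot), a 1-epoch × 25-task
fine-tuning stage, and 40 test tasks (2-way 8-shot, 8 queries per class).
Class pools: 24 exams per training class, 16 per validation class, 24 per
fine-tuning class, 20 per test class — enough for episodic sampling on
each client after the two-way split. These sizes are the package's chosen
CPU-scale operating point for its reference experiments.

## Limitations

The published real-data results — the per-plane accuracies around 85.3 /
82.1 / 71.0%, the backbone comparison, the baseline table, and the ROC
curves — are **not reproduced** here: they require the access-controlled
MRNet dataset, MedicalNet-pretrained 3-D ResNet-50 weights, and GPU-scale
training. What this package reproduces exactly is the metric arithmetic on
the published confusion counts, the preprocessing and encoding contracts,
and the qualitative claims (federation does not notably hurt accuracy;
overlapping-injury class pairs are harder) on its own synthetic data.
DICOM/NIfTI ingestion, secure aggregation, differential privacy, and
per-slice 2-D backbones are out of scope.
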