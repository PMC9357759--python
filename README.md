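# msstgcn

Multiscale spatio-temporal graph convolutional networks for
skeleton-based action recognition, in pure numpy.

Human actions can be classified from body-keypoint trajectories alone —
the output of a pose estimator such as OpenPose — which sidesteps the
lighting, viewpoint and background nuisances of raw video. This package
is for researchers and engineers who want a complete, dependency-light,
CPU-trainable implementation of that pipeline: skeleton graph
construction, pose-sequence preprocessing, the graph/temporal
convolution network itself with hand-written gradients, two-stream score
fusion, and a synthetic action generator so every part is testable
without downloading a dataset.

## The model

A skeleton sequence is a tensor `(C, T, V, M)` — channels, frames,
joints, persons. The network alternates two convolutions:

**Space.** With bone adjacency `A`, graph convolution uses the
normalized matrix `G = Λ^{-1/2}(A + I)Λ^{-1/2}` (`Λ` the degree matrix
with self-loops), split into three subsets by each neighbor's distance
to the skeleton's center of gravity — stationary (equal), centripetal
(closer), centrifugal (farther):

    f_out = Σ_z Θ_z( (G_z ⊙ W_z) f_in )

where `Θ_z` is a per-subset 1×1 channel transform and `W_z` a learnable
edge-importance mask (spatial attention over bones, initialized to
ones).

**Time.** Each block's multiscale temporal convolution (MS-TCN) runs two
parallel filter banks of half the channels each, with kernel extents `γ`
and `2γ` (default 8 and 16 frames), concatenated, batch-normalized,
residual-added and rectified — short- and long-duration movement
patterns in one block.

Ten such blocks, global average pooling and a softmax head form the
classifier (39,596 trainable parameters in the default configuration —
deliberately lightweight). Optionally, two streams — joint coordinates
and bone vectors — are trained independently and fused at the
probability level as `α·u_joint + (1−α)·u_bone` with `α = 0.6`.

## Worked example

```python
from msstgcn import (ModelConfig, SyntheticSpec, build_layout, build_model,
                     generate_dataset, stratified_split)
from msstgcn.training_eval import QUICK_PROFILE, evaluate, prepare_sequences, train
from dataclasses import replace

spec = SyntheticSpec(num_classes=4)            # classes differ in limb kinematics
layout = build_layout(spec.layout_name)        # 20-joint humanoid tree
seqs, labels = generate_dataset(spec, n_per_class=18, rng_seed=42)
tr_s, tr_y, te_s, te_y = stratified_split(seqs, labels, n_test_per_class=6, rng_seed=42)
xtr, ytr, channels = prepare_sequences(tr_s, layout)   # resample to 25 frames, center
xte, yte, _ = prepare_sequences(te_s, layout)

model = build_model(ModelConfig(num_classes=4, num_layers=3,
                                channel_plan=(8, 8, 16), gamma=4), seed=42)
model, history = train(model, (xtr, ytr),
                       replace(QUICK_PROFILE, epochs=18, warmup_epochs=5, seed=42),
                       channels=channels)
print([round(l, 3) for l in history.train_losses])
print(evaluate(model, xte, yte, ks=(1, 2)))
```

Output of this exact script (`examples/03_train_classifier.py` prints the
same run as a table):

```
[1.689, 1.546, 1.406, 1.344, 1.343, 1.353, 1.326, 1.293, 1.256, 1.219, 1.169, 1.1, 1.018, 0.928, 0.842, 0.763, 0.688, 0.618]
{1: 1.0, 2: 1.0}
```

The loss falls from its random-initialization value toward chance
(`ln 4 ≈ 1.386`) during the learning-rate warmup, then below it as the
temporal filters lock onto the class-specific swing frequencies; the
3-block model then classifies all 24 held-out sequences correctly.

The `examples/` directory holds one short script per capability: graph
construction and partitioning, synthetic data generation, training,
two-stream fusion, and OpenPose JSON ingestion. A thin CLI wraps the
same functions (`msstgcn generate / ingest / train / eval / fuse`).

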