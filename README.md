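# protovol

Few-shot (2-way, *k*-shot) classification of 3D grayscale image volumes —
knee-MRI-style exams in particular — for settings where only a handful of
labeled examples of a new condition exist. A 3D convolutional encoder maps
each volume to an embedding vector; a small labeled *support set* (k
examples per class) defines one *prototype* per class as the mean of its
support embeddings; an unlabeled *query* volume is assigned to the class
whose prototype is nearest in Euclidean distance. The encoder is trained
with the **generalized end-to-end (GE2E) loss**, which shapes the embedding
space directly for this nearest-prototype rule, and can first be pre-trained
with supervised cross-entropy on a related binary task whose labels are
plentiful, then transferred to the scarce task.

## The model

Write f_ij for the embedding of the j-th sample of label i in a training
batch of N labels × M samples, and C_k for the centroid (mean embedding) of
label k. With S_ji,k = w·cos(f_ij, C_k) + b (defaults w = 1, b = 0), each
embedding contributes

    L_ij = −S_ji,i + log Σ_{k=1..N} exp(S_ji,k)

and the batch loss is the sum over (i, j). Minimising it pulls every
embedding toward its own label's centroid and pushes it away from the other
centroids — exactly the intra-class compactness and inter-class separation
a prototype classifier needs. At evaluation time an episode draws k support
samples per class (patient-disjoint from the queries), builds prototypes,
and scores each query by the distance margin d_neg − d_pos, from which
SEN/SPE/ACC and the exact Mann–Whitney ROC-AUC are computed.

Because no GPU-scale dependency is assumed, the package ships its own small
numpy network engine (3D convolutions, ReLU, adaptive global average
pooling, linear head, Adam) with exact hand-derived gradients that are
pinned by finite-difference tests. The default `tiny3d` encoder (~19k
parameters, 16×32×32 input) trains with GE2E in seconds per hundred steps
on one CPU core; a `resnet_style` variant with skip connections is provided
for scale-up.

Real data enters through a CSV manifest (`exam_id, patient_id, label,
path`) pointing at NIfTI or `.npy` volumes, with axis convention
(depth, height, width), depth = slice axis. A synthetic generator produces
two-class lesion datasets (Gaussian background plus a contrast-controlled
ellipsoid or slab lesion, grouped by patient) so the whole pipeline runs
and is tested fully offline.

## Worked example

```python
import protovol as pv

# 1. Simulate a two-class lesion dataset (120 patients, one exam each)
data = pv.simulate_dataset(pv.SyntheticConfig(
    n_patients=120, lesion_contrast=3.0, seed=0))
train, test = pv.split_by_patient(data, (0.5, 0.5), seed=1)

# 2. Train a tiny 3D encoder with the GE2E loss
enc = pv.build_encoder(pv.EncoderSpec(), seed=2)
pv.train_ge2e(enc, train, pv.GE2EConfig(),
              pv.TrainSchedule(steps=300, seed=3))

# 3. Episodic 2-way k-shot evaluation on the held-out patients
for k in (2, 20):
    reports, agg = pv.evaluate_many(enc, test, pv.EpisodeConfig(k_shot=k),
                                    n_episodes=10, base_seed=4)
    print(f"k={k:2d}: AUC {agg['auc_mean']:.3f} +/- {agg['auc_sd']:.3f}  "
          f"ACC {agg['acc_mean']:.3f}  SEN {agg['sen_mean']:.3f}  "
          f"SPE {agg['spe_mean']:.3f}")
```

Output:

```
k= 2: AUC 0.856 +/- 0.009  ACC 0.788  SEN 0.863  SPE 0.717
k=20: AUC 0.864 +/- 0.087  ACC 0.830  SEN 0.922  SPE 0.755
```

Each line aggregates 10 episodes on patients never seen in training: with
only 2 labeled support volumes per class the nearest-prototype rule already
discriminates well (AUC 0.856), and a larger support set improves the
operating point (accuracy 0.79 → 0.83). `reports` holds the per-episode
confusion counts and metrics.

The same workflows are available from the shell:

```sh
protovol simulate   --config run.yaml --out data/
protovol pretrain   --config run.yaml --out runs/pre       # cross-entropy
protovol train-ge2e --config run.yaml --init-checkpoint runs/pre/encoder_pretrained.npz --out runs/ge2e
protovol evaluate   --config run.yaml --checkpoint runs/ge2e/encoder_ge2e.npz --k 2 --k 20 --k 40
protovol baseline   --config run.yaml --k 40               # supervised arm
```

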