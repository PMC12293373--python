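"""Generalized end-to-end (GE2E) embedding loss.

For a batch of embeddings f_ij (j-th sample of the i-th label, N labels ×
M samples per label), let C_k be the centroid (mean embedding) of label k
and S_ji,k = w·cos(f_ij, C_k) + b the (optionally scaled) cosine similarity
of each embedding to each centroid. The per-embedding loss is

    L_ij = −S_ji,i + log Σ_{k=1..N} exp(S_ji,k)

summed over the batch by default. Minimising it pulls each embedding toward
its own label's centroid and pushes it away from the other labels' centroids,
which is exactly the geometry a nearest-prototype classifier needs.

Defaults follow the plain formula literally: fixed w = 1, b = 0, no
self-exclusion. The refinements of the original speaker-verification GE2E —
a learned scale/bias and excluding f_ij from its own centroid when computing
S_ji,i — are available as options, off by default.

The gradient of the loss with respect to the embeddings (including the
dependence of the centroids on the embeddings) is derived analytically and
returned alongside the value, so encoders can be trained by plain
backpropagation; finite-difference tests pin its correctness.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import SampleSet
from .embedding import EncoderHandle
from .errors import ConfigurationError, DataError
from . import nn

_EPS_NORM = 1e-12


@dataclass(frozen=True)
class GE2EConfig:
    self_exclusion: bool = False
    scale: float = 1.0      # w
    bias: float = 0.0       # b
    scale_bias_learnable: bool = False
    reduction: str = "sum"  # "sum" (default) or "mean" over the N*M terms

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError("scale w must be > 0")
        if self.reduction not in ("sum", "mean"):
            raise ConfigurationError(f"unknown reduction {self.reduction!r}")


@dataclass
class EmbeddingBatch:
    """N × M × D tensor of embeddings f_ij plus the N label ids."""

    embeddings: np.ndarray
    label_ids: list[int]

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 3:
            raise DataError("embeddings must be an N×M×D tensor")
        n, m, _ = self.embeddings.shape
        if len(self.label_ids) != n:
            raise DataError(f"expected {n} label ids, got {len(self.label_ids)}")
        norms = np.linalg.norm(self.embeddings, axis=2)
        if np.any(norms < _EPS_NORM):
            raise DataError("zero-vector embedding: cosine similarity undefined")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.embeddings.shape  # type: ignore[return-value]


@dataclass
class CentroidSet:
    centroids: np.ndarray  # N × D


@dataclass
class SimilarityTensor:
    values: np.ndarray  # N × M × N, entry (i, j, k) = S_ji,k


def centroids(b: EmbeddingBatch, cfg: GE2EConfig | None = None) -> CentroidSet:
    """Per-label mean embeddings C_k.

    With ``self_exclusion`` the plain means are still returned here; the
    per-query variant (centroid of label i excluding f_ij itself, used only
    for the S_ji,i term) is applied inside :func:`similarity`.
    """
    cfg = cfg or GE2EConfig()
    n, m, _ = b.shape
    if cfg.self_exclusion and m < 2:
        raise ConfigurationError("self_exclusion requires M >= 2 samples per label")
    return CentroidSet(b.embeddings.mean(axis=1))


def _cosine(a: np.ndarray, bb: np.ndarray) -> np.ndarray:
    """Cosine of last-axis vectors; raises on zero norms instead of NaN."""
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(bb, axis=-1)
    if np.any(na < _EPS_NORM) or np.any(nb < _EPS_NORM):
        raise DataError("zero-norm vector in cosine similarity")
    return np.einsum("...d,...d->...", a, bb) / (na * nb)


def similarity(b: EmbeddingBatch, c: CentroidSet | None = None,
               cfg: GE2EConfig | None = None) -> SimilarityTensor:
    """S_ji,k = w·cos(f_ij, C_k) + b for every embedding/centroid pair."""
    cfg = cfg or GE2EConfig()
    if c is None:
        c = centroids(b, cfg)
    e = b.embeddings                      # N, M, D
    n, m, _ = e.shape
    s = _cosine(e[:, :, None, :], c.centroids[None, None, :, :])  # N, M, N
    if cfg.self_exclusion:
        if m < 2:
            raise ConfigurationError("self_exclusion requires M >= 2")
        excl = (m * c.centroids[:, None, :] - e) / (m - 1)        # N, M, D
        s_self = _cosine(e, excl)                                 # N, M
        idx = np.arange(n)
        s[idx, :, idx] = s_self
    return SimilarityTensor(cfg.scale * s + cfg.bias)


def ge2e_loss(b: EmbeddingBatch, cfg: GE2EConfig | None = None,
              return_grad: bool = False):
    """GE2E loss over a batch; optionally its gradient w.r.t. the embeddings.

    The log-sum-exp is computed with a max shift for numerical stability.
    With a single label (N = 1) each term collapses to −S + log eˢ = 0
    exactly. The returned gradient accounts for the centroids' dependence on
    the embeddings (including the self-exclusion variant).
    """
    cfg = cfg or GE2EConfig()
    n, m, d = b.shape
    e = b.embeddings
    c = centroids(b, cfg)
    s = similarity(b, c, cfg).values          # N, M, N

    smax = s.max(axis=2, keepdims=True)
    lse = smax[:, :, 0] + np.log(np.exp(s - smax).sum(axis=2))
    idx = np.arange(n)
    per_term = -s[idx, :, idx] + lse          # N, M
    total = per_term.sum()
    scale_red = 1.0 / (n * m) if cfg.reduction == "mean" else 1.0
    loss = float(scale_red * total)
    if not return_grad:
        return loss

    # dL/dS_ji,k = softmax_k(S_ji,:) − 1[k = i]
    p = np.exp(s - lse[:, :, None])           # N, M, N
    ds = p.copy()
    ds[idx, :, idx] -= 1.0

    w = cfg.scale
    norm_e = np.linalg.norm(e, axis=2)                    # N, M
    grad = np.zeros_like(e)

    cent = c.centroids                                     # N, D
    norm_c = np.linalg.norm(cent, axis=1)                  # N
    cos_full = _cosine(e[:, :, None, :], cent[None, None, :, :])   # N, M, N

    # which (i, j, k) entries use the plain centroid C_k
    use_plain = np.ones((n, m, n), dtype=bool)
    if cfg.self_exclusion:
        use_plain[idx, :, idx] = False
    dsp = ds * use_plain

    # d cos(f, C_k)/df = C_k/(|f||C_k|) − cos·f/|f|²
    inv_fc = 1.0 / (norm_e[:, :, None] * norm_c[None, None, :])    # N, M, N
    grad += w * np.einsum("ijk,ijk,kd->ijd", dsp, inv_fc, cent, optimize=True)
    grad -= w * (dsp * cos_full / norm_e[:, :, None] ** 2).sum(axis=2)[:, :, None] * e

    # d cos(f, C_k)/dC_k = f/(|f||C_k|) − cos·C_k/|C_k|², then C_k = mean_j f_kj
    gC = w * np.einsum("ijk,ijk,ijd->kd", dsp, inv_fc, e, optimize=True)
    gC -= w * (np.einsum("ijk,ijk->k", dsp, cos_full)
               / norm_c ** 2)[:, None] * cent
    grad += gC[:, None, :] / m

    if cfg.self_exclusion:
        excl = (m * cent[:, None, :] - e) / (m - 1)        # N, M, D
        norm_x = np.linalg.norm(excl, axis=2)
        cos_x = _cosine(e, excl)                           # N, M
        ds_self = ds[idx, :, idx]                          # N, M
        inv_fx = 1.0 / (norm_e * norm_x)
        grad += w * (ds_self * inv_fx)[:, :, None] * excl
        grad -= w * (ds_self * cos_x / norm_e ** 2)[:, :, None] * e
        gx = w * (ds_self * inv_fx)[:, :, None] * e \
            - w * (ds_self * cos_x / norm_x ** 2)[:, :, None] * excl   # N, M, D
        # dC_excl[i,j]/df_ij' = 1/(M−1) for j' ≠ j, 0 for j' = j
        grad += (gx.sum(axis=1, keepdims=True) - gx) / (m - 1)

    return loss, scale_red * grad


@dataclass(frozen=True)
class TrainSchedule:
    n_labels: int = 2
    m_per_label: int = 4   # N × M = 8 volumes per step
    steps: int = 400
    learning_rate: float = 1e-3
    seed: int = 0


def train_ge2e(enc: EncoderHandle, train: SampleSet,
               cfg: GE2EConfig | None = None,
               sched: TrainSchedule | None = None,
               curve_path: str | Path | None = None) -> EncoderHandle:
    """Train an encoder in place with the GE2E loss.

    Each step samples M volumes from each of N labels, embeds them, computes
    the loss gradient w.r.t. the embeddings analytically and backpropagates
    it through the encoder (Adam). Deterministic given the schedule seed and
    fixed thread settings. Optionally logs (step, loss) to a CSV.
    """
    cfg = cfg or GE2EConfig()
    sched = sched or TrainSchedule()
    counts: dict[int, int] = {}
    for s in train:
        counts[s.label] = counts.get(s.label, 0) + 1
    labels = sorted(counts)
    if len(labels) < sched.n_labels:
        raise DataError(
            f"training pool has {len(labels)} label(s); schedule needs "
            f"{sched.n_labels}")
    for lab in labels[:sched.n_labels]:
        if counts[lab] < sched.m_per_label:
            raise DataError(
                f"label {lab} has {counts[lab]} samples; schedule needs "
                f"{sched.m_per_label} per label")

    rng = np.random.default_rng(sched.seed)
    by_label: dict[int, list] = {}
    for s in train:
        by_label.setdefault(s.label, []).append(s)
    use_labels = labels[:sched.n_labels]

    opt = nn.Adam(enc.net, lr=sched.learning_rate)
    curve: list[tuple[int, float]] = []
    for step in range(sched.steps):
        vols, structure = [], []
        for lab in use_labels:
            pool = by_label[lab]
            pick = rng.choice(len(pool), size=sched.m_per_label,
                              replace=len(pool) < sched.m_per_label)
            structure.append([pool[i] for i in pick])
        for row in structure:
            vols.extend(s.volume.voxels for s in row)
        emb = enc.forward(np.stack(vols), train=True)      # (N*M, D)
        batch = EmbeddingBatch(
            emb.reshape(sched.n_labels, sched.m_per_label, -1),
            label_ids=list(use_labels))
        loss, grad = ge2e_loss(batch, cfg, return_grad=True)
        opt.zero_grad()
        enc.backward(grad.reshape(emb.shape))
        opt.step()
        curve.append((step, loss))

    if curve_path is not None:
        with open(curve_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "loss"])
            writer.writerows(curve)
    return enc
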