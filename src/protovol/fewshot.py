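"""Episodic 2-way k-shot evaluation with nearest-prototype classification.

An episode draws exactly k support samples per class from a pool and uses
the remaining eligible samples (or a fixed number) as queries. Per-class
prototypes are the unweighted means of the support embeddings; a query is
assigned to the class whose prototype is nearest in Euclidean distance,
with ties broken toward the negative class. The continuous ROC score is the
distance margin d_neg − d_pos (positive ⇔ closer to the positive
prototype); a softmax over negative distances is available as an option and
is monotone in the margin for two classes, hence AUC-identical.

Patient-level disjointness between support and query is on by default so no
patient can leak reference information into its own evaluation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import SampleSet
from .embedding import EmbeddingVector, EncoderHandle, embed_batch
from .errors import ConfigurationError, DataError, EpisodeError


@dataclass(frozen=True)
class EpisodeConfig:
    k_shot: int = 20
    n_query: int | str = "all_remaining"
    patient_disjoint_support_query: bool = True
    seed: int = 0
    n_way: int = 2  # fixed; binary tasks only

    def __post_init__(self) -> None:
        if self.n_way != 2:
            raise ConfigurationError("only 2-way episodes are supported")
        if self.k_shot < 1:
            raise ConfigurationError("k_shot must be >= 1")
        if self.n_query != "all_remaining" and (
                not isinstance(self.n_query, int) or self.n_query < 1):
            raise ConfigurationError(
                "n_query must be a positive int or 'all_remaining'")


@dataclass
class Episode:
    support: SampleSet
    query: SampleSet
    config: EpisodeConfig


@dataclass
class PrototypeSet:
    """Per-class mean support embedding; exactly one entry per class."""

    prototypes: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if sorted(self.prototypes) != [0, 1]:
            raise ConfigurationError(
                f"expected prototypes for classes {{0, 1}}, got "
                f"{sorted(self.prototypes)}")


@dataclass
class QueryResult:
    exam_id: str
    true_label: int
    predicted_label: int
    score: float                 # d_neg − d_pos; higher = more positive-class
    distances: dict[int, float]


def build_episode(pool: SampleSet, cfg: EpisodeConfig) -> Episode:
    """Sample one support/query episode from a pool, deterministically.

    Support samples are drawn per class with a seeded generator; queries are
    the remaining samples, excluding (by default) every exam of any patient
    already in the support set.
    """
    rng = np.random.default_rng(cfg.seed)
    support_idx: list[int] = []
    for label in (0, 1):
        candidates = [i for i, s in enumerate(pool) if s.label == label]
        if len(candidates) < cfg.k_shot:
            raise EpisodeError(
                f"class {label} has {len(candidates)} samples in pool "
                f"{pool.name!r}; k={cfg.k_shot} support samples required")
        pick = rng.choice(len(candidates), size=cfg.k_shot, replace=False)
        support_idx.extend(candidates[i] for i in sorted(pick))
    support = [pool[i] for i in support_idx]
    support_patients = {s.patient_id for s in support}
    support_exams = {s.exam_id for s in support}

    eligible = []
    for i, s in enumerate(pool):
        if s.exam_id in support_exams:
            continue
        if cfg.patient_disjoint_support_query and s.patient_id in support_patients:
            continue
        eligible.append(i)
    if cfg.n_query == "all_remaining":
        query_idx = eligible
    else:
        if len(eligible) < cfg.n_query:
            raise EpisodeError(
                f"only {len(eligible)} eligible query samples, "
                f"{cfg.n_query} requested")
        pick = rng.choice(len(eligible), size=cfg.n_query, replace=False)
        query_idx = [eligible[i] for i in sorted(pick)]
    if not query_idx:
        raise EpisodeError("episode has no query samples; pool too small for k")
    return Episode(
        support=SampleSet(support, name=f"{pool.name}/support"),
        query=SampleSet([pool[i] for i in query_idx], name=f"{pool.name}/query"),
        config=cfg)


def prototypes(support_embeddings: Sequence[tuple[EmbeddingVector, int]],
               l2_normalize: bool = False) -> PrototypeSet:
    """Unweighted per-class mean of support embeddings.

    By default the mean is taken on raw embeddings; ``l2_normalize``
    normalises each embedding to unit length before averaging.
    """
    by_class: dict[int, list[np.ndarray]] = {}
    for ev, label in support_embeddings:
        vec = ev.values
        if l2_normalize:
            vec = vec / np.linalg.norm(vec)
        by_class.setdefault(int(label), []).append(vec)
    if sorted(by_class) != [0, 1]:
        raise DataError(
            f"support set must contain both classes, got {sorted(by_class)}")
    return PrototypeSet({c: np.mean(vecs, axis=0) for c, vecs in by_class.items()})


def classify_query(q: EmbeddingVector, p: PrototypeSet) -> QueryResult:
    """Nearest-prototype assignment by Euclidean distance.

    Ties (equal distances) go to class 0, the conservative
    negative/intact call. ``true_label`` is filled by the caller; here it is
    set to −1 as a sentinel.
    """
    dims = {c: len(v) for c, v in p.prototypes.items()}
    if any(d != len(q.values) for d in dims.values()):
        raise DataError(
            f"query {q.exam_id!r} has dim {len(q.values)}, prototypes have {dims}")
    dist = {c: float(np.linalg.norm(q.values - v))
            for c, v in p.prototypes.items()}
    predicted = 1 if dist[1] < dist[0] else 0
    return QueryResult(exam_id=q.exam_id, true_label=-1,
                       predicted_label=predicted,
                       score=dist[0] - dist[1], distances=dist)


def softmax_scores(result: QueryResult) -> dict[int, float]:
    """Posterior-style scores softmax(−d_c); optional alternative to the margin."""
    d = np.array([result.distances[0], result.distances[1]])
    z = np.exp(-(d - d.min()))
    z /= z.sum()
    return {0: float(z[0]), 1: float(z[1])}


def evaluate_episode(enc: EncoderHandle, ep: Episode,
                     l2_normalize_prototypes: bool = False) -> list[QueryResult]:
    """Embed support and query sets (inference mode) and classify every query."""
    sup = [(ev, label) for ev, label, _ in embed_batch(enc, ep.support)]
    proto = prototypes(sup, l2_normalize=l2_normalize_prototypes)
    results = []
    for ev, label, _ in embed_batch(enc, ep.query):
        r = classify_query(ev, proto)
        r.true_label = int(label)
        results.append(r)
    return results


def evaluate_many(enc: EncoderHandle, pool: SampleSet, cfg: EpisodeConfig,
                  n_episodes: int, base_seed: int):
    """Evaluate ``n_episodes`` episodes; episode e uses seed base_seed + e.

    Returns (per-episode MetricsReport list, aggregate dict of mean and SD
    for acc/sen/spe/auc over episodes). The pool is embedded once and
    reused across episodes, which is exact: embedding is deterministic and
    per-sample.
    """
    from dataclasses import replace
    from .metrics import summarize

    emb_by_exam = {ev.exam_id: (ev, label)
                   for ev, label, _ in embed_batch(enc, pool)}
    reports = []
    for e in range(n_episodes):
        ep = build_episode(pool, replace(cfg, seed=base_seed + e))
        sup = [emb_by_exam[x] for x in ep.support.exam_ids]
        proto = prototypes(sup)
        results = []
        for exam_id in ep.query.exam_ids:
            ev, label = emb_by_exam[exam_id]
            r = classify_query(ev, proto)
            r.true_label = int(label)
            results.append(r)
        reports.append(summarize(results))
    agg = {}
    for metric in ("acc", "sen", "spe", "auc"):
        vals = [getattr(r, metric) for r in reports if getattr(r, metric) is not None]
        agg[f"{metric}_mean"] = float(np.mean(vals)) if vals else None
        agg[f"{metric}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return reports, agg


def write_results_csv(results: Sequence[QueryResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["exam_id", "true", "pred", "score", "d_pos", "d_neg"])
        for r in results:
            writer.writerow([r.exam_id, r.true_label, r.predicted_label,
                             f"{r.score:.10g}", f"{r.distances[1]:.10g}",
                             f"{r.distances[0]:.10g}"])
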