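"""Topic modeling over concept-bag clinical notes.

Notes arrive as bags of concept identifiers (one mapping concept -> count
per note).  The pipeline is:

1. :func:`build_vocabulary` — keep concepts whose document frequency lies
   strictly between ``min_df`` (default 10%) and ``max_df`` (default 70%).
2. :func:`fit_topic_model` — latent Dirichlet allocation by collapsed Gibbs
   sampling: ``passes`` full sweeps (default 250) over the token stream with
   symmetric Dirichlet smoothing ``alpha`` (document-topic) and ``beta``
   (topic-concept); point estimates phi and theta from the smoothed final
   counts.  Deterministic given a seed.
3. :func:`topic_coherence` — UMass document co-occurrence coherence of each
   topic's top concepts, used by :func:`select_topic_count`.
4. :func:`encounter_topic_distribution` / :func:`class_topic_matrix` — the
   note -> encounter -> latent-class aggregation that validates subtypes:
   each class is summarized by the mean topic probability over its
   encounters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .lca import match_classes  # noqa: F401  (re-exported convenience in pipelines)

__all__ = [
    "ConceptVocabulary",
    "ConceptCorpus",
    "TopicModelParams",
    "build_vocabulary",
    "corpus_from_notes",
    "fit_topic_model",
    "topic_coherence",
    "select_topic_count",
    "encounter_topic_distribution",
    "class_topic_matrix",
    "match_topics",
]


@dataclass(frozen=True)
class ConceptVocabulary:
    """Retained concepts (ordered) with their document frequencies."""

    concepts: tuple[str, ...]
    doc_freq: np.ndarray
    min_df: float
    max_df: float

    @property
    def size(self) -> int:
        return len(self.concepts)

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.concepts)}


@dataclass
class ConceptCorpus:
    """Dense note x concept count matrix over a filtered vocabulary.

    ``empty`` flags notes that lost every concept to the vocabulary filter;
    they are skipped during sampling and receive uniform topic estimates.
    """

    vocabulary: ConceptVocabulary
    note_ids: np.ndarray
    encounter_ids: np.ndarray
    counts: np.ndarray  # D x V, int32

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def empty(self) -> np.ndarray:
        return self.counts.sum(axis=1) == 0

    def token_stream(self) -> tuple[np.ndarray, np.ndarray]:
        """(word ids, doc ids) with counts expanded into repeated tokens."""
        d_idx, w_idx = np.nonzero(self.counts)
        reps = self.counts[d_idx, w_idx]
        return np.repeat(w_idx, reps).astype(np.int32), np.repeat(d_idx, reps).astype(np.int32)


@dataclass
class TopicModelParams:
    K: int
    phi: np.ndarray    # K x V
    theta: np.ndarray  # D x K
    alpha: float
    beta: float
    passes: int
    seed: int


def build_vocabulary(notes: pd.DataFrame, min_df: float = 0.10, max_df: float = 0.70) -> ConceptVocabulary:
    """Concepts kept iff ``min_df < df < max_df`` (both bounds strict).

    ``df`` is the fraction of notes containing the concept at least once.
    """
    if len(notes) == 0:
        raise ValueError("empty note table")
    n_notes = len(notes)
    df_counts: dict[str, int] = {}
    for bag in notes["concept_counts"]:
        for concept in bag:
            df_counts[concept] = df_counts.get(concept, 0) + 1
    kept = sorted(c for c, k in df_counts.items() if min_df < k / n_notes < max_df)
    freqs = np.array([df_counts[c] / n_notes for c in kept])
    return ConceptVocabulary(concepts=tuple(kept), doc_freq=freqs, min_df=min_df, max_df=max_df)


def corpus_from_notes(notes: pd.DataFrame, vocabulary: ConceptVocabulary) -> ConceptCorpus:
    index = vocabulary.index()
    D, V = len(notes), vocabulary.size
    counts = np.zeros((D, V), dtype=np.int32)
    for i, bag in enumerate(notes["concept_counts"]):
        for concept, cnt in bag.items():
            if cnt < 0:
                raise ValueError(f"negative concept count in note {notes['note_id'].iat[i]}")
            j = index.get(concept)
            if j is not None:
                counts[i, j] = cnt
    empties = int((counts.sum(axis=1) == 0).sum())
    if empties:
        warnings.warn(f"{empties} notes are empty after vocabulary filtering")
    return ConceptCorpus(
        vocabulary=vocabulary,
        note_ids=notes["note_id"].to_numpy(),
        encounter_ids=notes["encounter_id"].to_numpy(),
        counts=counts,
    )


@njit(cache=False)
def _gibbs_pass(words, docs, z, ndk, nwk, nk, alpha, beta, u, probs):  # pragma: no cover
    V = nwk.shape[0]
    K = nk.shape[0]
    for t in range(words.shape[0]):
        w = words[t]
        d = docs[t]
        k = z[t]
        ndk[d, k] -= 1
        nwk[w, k] -= 1
        nk[k] -= 1
        total = 0.0
        for kk in range(K):
            p = (ndk[d, kk] + alpha) * (nwk[w, kk] + beta) / (nk[kk] + V * beta)
            probs[kk] = p
            total += p
        r = u[t] * total
        acc = 0.0
        knew = K - 1
        for kk in range(K):
            acc += probs[kk]
            if acc >= r:
                knew = kk
                break
        z[t] = knew
        ndk[d, knew] += 1
        nwk[w, knew] += 1
        nk[knew] += 1


def _cooccurrence_clusters(counts: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Cluster concepts into K groups by document co-occurrence (spectral
    embedding of the co-occurrence graph + k-means).  Used to seed the Gibbs
    chain close to the corpus's block structure."""
    from scipy.cluster.vq import kmeans2

    V = counts.shape[1]
    K = min(K, V)
    binary = (counts > 0).astype(np.float64)
    cooc = binary.T @ binary
    np.fill_diagonal(cooc, 0.0)
    deg = np.maximum(cooc.sum(axis=1), 1e-12)
    sim = cooc / np.sqrt(deg[:, None] * deg[None, :])  # normalized adjacency
    vals, vecs = np.linalg.eigh(sim)
    emb = vecs[:, -K:]
    norms = np.maximum(np.linalg.norm(emb, axis=1, keepdims=True), 1e-12)
    emb = emb / norms
    _centroids, labels = kmeans2(emb, K, minit="++", seed=rng, iter=50)
    return labels.astype(np.int32)


def _joint_loglik(ndk, nwk, nk, nd, alpha, beta) -> float:
    """Collapsed joint log p(w, z) up to constants shared across restarts."""
    from scipy.special import gammaln

    V, K = nwk.shape
    word_part = float(
        K * gammaln(V * beta) - gammaln(nk + V * beta).sum() + gammaln(nwk + beta).sum()
        - V * K * gammaln(beta)
    )
    doc_part = float(gammaln(ndk + alpha).sum() - gammaln(nd + K * alpha).sum())
    return word_part + doc_part


def fit_topic_model(
    corpus: ConceptCorpus,
    K: int,
    passes: int = 250,
    alpha: float = 0.1,
    beta: float = 0.01,
    seed: int = 0,
    init: str = "cooccurrence",
    n_starts: int = 3,
) -> TopicModelParams:
    """Collapsed Gibbs LDA: ``passes`` full sweeps, seeded and deterministic.

    ``init="cooccurrence"`` (default) seeds each token's topic from a
    document-co-occurrence clustering of the vocabulary, which steers the
    chain away from the split/duplicate-topic local optima that plain random
    initialization falls into; ``init="random"`` gives the vanilla chain.
    ``n_starts`` restarts are run and the one with the highest collapsed
    joint log-likelihood log p(w, z) is kept.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if corpus.vocabulary.size == 0:
        raise ValueError("empty vocabulary")
    if init not in ("cooccurrence", "random"):
        raise ValueError(f"unknown init: {init!r}")
    D, V = corpus.counts.shape
    if K > D:
        warnings.warn(f"K={K} exceeds the number of documents ({D}); fitting anyway")
    words, docs = corpus.token_stream()
    n_tokens = words.size
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for start in range(max(n_starts, 1)):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71, start]))
        if init == "cooccurrence" and K > 1 and n_tokens:
            word_cluster = _cooccurrence_clusters(corpus.counts, K, rng)
            z = word_cluster[words].astype(np.int32)
        else:
            z = rng.integers(0, K, size=n_tokens).astype(np.int32)
        ndk = np.zeros((D, K), dtype=np.float64)
        nwk = np.zeros((V, K), dtype=np.float64)
        np.add.at(ndk, (docs, z), 1.0)
        np.add.at(nwk, (words, z), 1.0)
        nk = nwk.sum(axis=0)
        probs = np.empty(K, dtype=np.float64)
        for _sweep in range(passes):
            u = rng.random(n_tokens)
            _gibbs_pass(words, docs, z, ndk, nwk, nk, alpha, beta, u, probs)
        score = _joint_loglik(ndk, nwk, nk, ndk.sum(axis=1), alpha, beta)
        if best is None or score > best[0]:
            best = (score, ndk, nwk, nk)
    _score, ndk, nwk, nk = best
    phi = (nwk.T + beta) / (nk[:, None] + V * beta)
    theta = (ndk + alpha) / (ndk.sum(axis=1, keepdims=True) + K * alpha)
    theta[corpus.empty] = 1.0 / K
    return TopicModelParams(K=K, phi=phi, theta=theta, alpha=alpha, beta=beta, passes=passes, seed=seed)


def topic_coherence(
    model: TopicModelParams, corpus: ConceptCorpus, top_n: int = 10
) -> tuple[np.ndarray, float]:
    """UMass coherence per topic and its mean over topics.

    For each topic's ``top_n`` concepts (by phi), coherence is
    ``sum_{m<l} log((D(w_m, w_l) + 1) / D(w_l))`` with D(.) document
    (co-)occurrence counts in ``corpus``.
    """
    V = corpus.vocabulary.size
    if top_n > V:
        warnings.warn(f"top_n={top_n} exceeds vocabulary size {V}; clipping")
        top_n = V
    binary = (corpus.counts > 0).astype(np.float64)
    cooc = binary.T @ binary               # V x V document co-occurrence
    docfreq = np.maximum(binary.sum(axis=0), 1.0)
    scores = np.zeros(model.K)
    for k in range(model.K):
        top = np.argsort(-model.phi[k])[:top_n]
        s = 0.0
        for m in range(1, top_n):
            for l in range(m):
                s += np.log((cooc[top[m], top[l]] + 1.0) / docfreq[top[l]])
        scores[k] = s
    return scores, float(scores.mean())


def select_topic_count(
    corpus: ConceptCorpus,
    k_range,
    passes: int = 250,
    alpha: float = 0.1,
    beta: float = 0.01,
    seed: int = 0,
    top_n: int = 10,
    tolerance: float = 0.02,
) -> tuple[pd.DataFrame, int]:
    """Coherence curve over ``k_range`` and the selected topic count.

    The selected K is the smallest one whose mean coherence comes within a
    relative ``tolerance`` (fraction of the best score's magnitude) of the
    maximum: coherence plateaus beyond the true topic count on separable
    corpora, so a plain argmax is sampling noise on the plateau.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    rows = []
    for K in ks:
        model = fit_topic_model(corpus, K, passes=passes, alpha=alpha, beta=beta, seed=seed + 7 * K)
        _scores, mean = topic_coherence(model, corpus, top_n=top_n)
        rows.append({"K": K, "mean_coherence": mean})
    curve = pd.DataFrame(rows)
    best = curve["mean_coherence"].max()
    threshold = best - tolerance * abs(best)
    chosen = int(curve.loc[curve["mean_coherence"] >= threshold, "K"].iloc[0])
    return curve, chosen


def encounter_topic_distribution(model: TopicModelParams, corpus: ConceptCorpus) -> pd.DataFrame:
    """Per-encounter topic distribution: unweighted mean of theta over the
    encounter's notes (uniform with a warning for encounters whose notes all
    emptied out)."""
    df = pd.DataFrame(model.theta)
    df["encounter_id"] = corpus.encounter_ids
    df["empty"] = corpus.empty
    all_empty = df.groupby("encounter_id")["empty"].all()
    if all_empty.any():
        warnings.warn(
            f"{int(all_empty.sum())} encounters have no surviving notes; uniform distribution assigned"
        )
    agg = df.drop(columns="empty").groupby("encounter_id").mean()
    agg = agg.div(agg.sum(axis=1), axis=0)
    return agg


def class_topic_matrix(encounter_topics: pd.DataFrame, class_labels: pd.Series) -> pd.DataFrame:
    """C x K matrix: mean topic probability over the encounters of each class.

    ``class_labels`` is indexed by encounter_id and must cover every
    encounter in ``encounter_topics``; empty classes are omitted with a
    warning.
    """
    labels = class_labels.reindex(encounter_topics.index)
    if labels.isna().any():
        missing = encounter_topics.index[labels.isna()].tolist()[:10]
        raise ValueError(f"class labels missing for encounters {missing}")
    out = encounter_topics.groupby(labels).mean()
    present = set(out.index)
    expected = set(pd.unique(class_labels))
    for c in sorted(expected - present):
        warnings.warn(f"class {c} has no encounters with topics; row omitted")
    return out


def match_topics(phi: np.ndarray, reference_phi: np.ndarray) -> np.ndarray:
    """Permutation entry k = fitted topic matched to reference topic k
    (optimal assignment under L1 distance between topic-concept rows)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(reference_phi[:, None, :] - phi[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(phi.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm
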