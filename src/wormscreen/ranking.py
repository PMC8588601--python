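"""Literature-similarity ranking of candidate drugs against a known set.

Documents are embedded as TF-IDF vectors over a capped vocabulary, each
entity (drug) is summarised by the centroid of its documents, pairwise
cosine similarity between centroids defines a weighted graph, and a
random walk with restart (RWR) over that graph scores every candidate by
proximity to the whole known set. Leave-one-out cross-validation puts
each known entity back among the candidates in turn and measures how
well the walk retrieves it (ROC/AUC, average precision, rank-sum test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import stats

DEFAULT_VOCAB_SIZE = 20_000
DEFAULT_RESTART = 0.15


@dataclass
class Corpus:
    """Tokenised documents with entity ownership and known/candidate roles.

    Parameters
    ----------
    documents : dict
        doc_id -> list of tokens.
    entity_map : dict
        entity -> set of doc_ids owned by that entity.
    roles : dict
        entity -> "known" or "candidate".
    """

    documents: dict[str, list[str]]
    entity_map: dict[str, set[str]]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for entity, docs in self.entity_map.items():
            if not docs:
                raise ValueError(f"entity {entity!r} has no documents")
            missing = docs - self.documents.keys()
            if missing:
                raise ValueError(f"entity {entity!r} references unknown docs {missing}")
        if set(self.roles) != set(self.entity_map):
            raise ValueError("roles must cover exactly the entities in entity_map")
        bad = {r for r in self.roles.values()} - {"known", "candidate"}
        if bad:
            raise ValueError(f"invalid roles {bad}")

    @property
    def known(self) -> list[str]:
        return sorted(e for e, r in self.roles.items() if r == "known")

    @property
    def candidates(self) -> list[str]:
        return sorted(e for e, r in self.roles.items() if r == "candidate")

    def reassign(self, entity: str, role: str) -> "Corpus":
        """Copy of the corpus with one entity's role changed (for LOO)."""
        roles = dict(self.roles)
        roles[entity] = role
        return Corpus(self.documents, self.entity_map, roles)


@dataclass
class Vocabulary:
    terms: list[str]
    df: np.ndarray  # document frequency per term
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class RankedList:
    """Candidates ordered by diffusion score (descending, ties lexicographic)."""

    candidates: list[str]
    scores: dict[str, float]  # score per entity (knowns included), sums to 1

    def rank_of(self, entity: str) -> int:
        """1-based rank of ``entity`` among the candidates."""
        return self.candidates.index(entity) + 1


@dataclass
class LooValidation:
    roc_points: np.ndarray
    auc: float
    pr_points: np.ndarray
    average_precision: float
    ranksum_p: float
    holdout_ranks: dict[str, int]
    holdout_scores: dict[str, float]
    negative_scores: dict[str, float]


def build_vocabulary(corpus: Corpus, size: int = DEFAULT_VOCAB_SIZE) -> Vocabulary:
    """Keep the ``size`` most frequent terms (total corpus count).

    Frequency ties are broken lexicographically so the vocabulary is
    deterministic.
    """
    if size < 1:
        raise ValueError("vocabulary size must be >= 1")
    if not corpus.documents:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    df_counts: dict[str, int] = {}
    for tokens in corpus.documents.values():
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        for t in set(tokens):
            df_counts[t] = df_counts.get(t, 0) + 1
    terms = sorted(counts, key=lambda t: (-counts[t], t))[:size]
    df = np.array([df_counts[t] for t in terms], dtype=float)
    return Vocabulary(terms=terms, df=df)


def tfidf_vectors(
    corpus: Corpus,
    vocab: Vocabulary,
    *,
    length_normalize: bool = True,
    smooth_idf: bool = True,
) -> dict[str, np.ndarray]:
    """TF-IDF vector per document over the vocabulary.

    weight(t, d) = tf(t, d) * idf(t) with tf the length-normalised count
    (count(t, d) / len(d)) and idf = ln((1 + N) / (1 + df(t))) by default;
    ``length_normalize=False`` uses raw counts and ``smooth_idf=False``
    the unsmoothed ln(N / df). Out-of-vocabulary tokens are ignored; an
    empty (or all-OOV) document yields a zero vector with a warning.
    """
    n_docs = len(corpus.documents)
    if smooth_idf:
        idf = np.log((1.0 + n_docs) / (1.0 + vocab.df))
    else:
        idf = np.log(n_docs / vocab.df)
    vectors: dict[str, np.ndarray] = {}
    for doc_id, tokens in corpus.documents.items():
        vec = np.zeros(len(vocab))
        for t in tokens:
            i = vocab.index.get(t)
            if i is not None:
                vec[i] += 1.0
        if length_normalize:
            if len(tokens) > 0:
                vec /= len(tokens)
        if vec.sum() == 0:
            warnings.warn(f"document {doc_id!r} has no in-vocabulary tokens; zero vector")
        vectors[doc_id] = vec * idf
    return vectors


def entity_centroids(
    doc_vectors: dict[str, np.ndarray], corpus: Corpus
) -> dict[str, np.ndarray]:
    """Arithmetic mean of each entity's document vectors."""
    return {
        entity: np.mean([doc_vectors[d] for d in sorted(docs)], axis=0)
        for entity, docs in corpus.entity_map.items()
    }


@dataclass
class SimilarityGraph:
    entities: list[str]
    S: np.ndarray  # symmetric, entries in [0, 1]

    def index_of(self, entity: str) -> int:
        return self.entities.index(entity)


def similarity_graph(centroids: dict[str, np.ndarray]) -> SimilarityGraph:
    """Pairwise cosine similarity between centroids, truncated at 0.

    A zero centroid has similarity 0 to everything, including itself
    (its diagonal entry is 0 rather than 1).
    """
    if len(centroids) < 2:
        raise ValueError("need at least two entities")
    entities = sorted(centroids)
    M = np.array([centroids[e] for e in entities], dtype=float)
    norms = np.linalg.norm(M, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = M / safe[:, None]
    S = np.clip(unit @ unit.T, 0.0, None)
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    np.fill_diagonal(S, np.where(norms > 0, 1.0, 0.0))
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)  # symmetrize against float noise
    return SimilarityGraph(entities=entities, S=S)


def _walk_matrix(graph: SimilarityGraph) -> np.ndarray:
    """Row-normalised transition matrix; zero rows noted for restart teleport."""
    row_sums = graph.S.sum(axis=1)
    W = np.zeros_like(graph.S)
    nz = row_sums > 0
    W[nz] = graph.S[nz] / row_sums[nz, None]
    return W


def diffusion_rank(
    graph: SimilarityGraph,
    known: "set[str] | list[str]",
    *,
    alpha: float = DEFAULT_RESTART,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> RankedList:
    """Random walk with restart from the known set over the similarity graph.

    Iterates s <- alpha * e + (1 - alpha) * W' s, where e is uniform over
    the known entities and W is the row-normalised similarity matrix
    (zero rows teleport their mass back to e), until the L1 change drops
    below ``tol``. Candidates are ranked by stationary score, descending,
    ties broken lexicographically.
    """
    known = sorted(set(known))
    if not known:
        raise ValueError("known set is empty")
    missing = set(known) - set(graph.entities)
    if missing:
        raise ValueError(f"known entities not in graph: {missing}")
    n = len(graph.entities)
    idx = {e: i for i, e in enumerate(graph.entities)}
    e = np.zeros(n)
    e[[idx[k] for k in known]] = 1.0 / len(known)
    W = _walk_matrix(graph)
    dangling = graph.S.sum(axis=1) == 0

    known_rows = [idx[k] for k in known]
    off_diag = graph.S[np.ix_(known_rows, [i for i in range(n) if i not in set(known_rows)])]
    if off_diag.size and not off_diag.any():
        warnings.warn("known set has zero similarity to all candidates; candidate scores tie")

    s = e.copy()
    for _ in range(max_iter):
        flow = W.T @ s + e * s[dangling].sum()  # dangling mass restarts
        s_new = alpha * e + (1.0 - alpha) * flow
        if np.abs(s_new - s).sum() < tol:
            s = s_new
            break
        s = s_new
    else:
        raise RuntimeError(
            f"RWR did not converge in {max_iter} iterations "
            f"(residual {np.abs(W.T @ s + e * s[dangling].sum() - s).sum():.3e})"
        )
    scores = {ent: float(s[idx[ent]]) for ent in graph.entities}
    candidates = [ent for ent in graph.entities if ent not in set(known)]
    candidates.sort(key=lambda ent: (-scores[ent], ent))
    return RankedList(candidates=candidates, scores=scores)


def rank_candidates(
    corpus: Corpus,
    *,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    alpha: float = DEFAULT_RESTART,
) -> RankedList:
    """Full pipeline: vocabulary -> TF-IDF -> centroids -> graph -> RWR."""
    vocab = build_vocabulary(corpus, vocab_size)
    vectors = tfidf_vectors(corpus, vocab)
    centroids = entity_centroids(vectors, corpus)
    graph = similarity_graph(centroids)
    return diffusion_rank(graph, corpus.known, alpha=alpha)


def loo_validate(
    corpus: Corpus,
    *,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    alpha: float = DEFAULT_RESTART,
) -> LooValidation:
    """Leave-one-out retrieval validation of the diffusion ranking.

    Each known entity is moved to the candidate pool in turn and
    re-ranked by the remaining knowns; its score and 1-based rank among
    candidates are recorded. ROC and PR curves treat the held-out knowns
    as positives and the never-known candidates — scored once under the
    full known set — as negatives. The one-tailed rank-sum test asks
    whether held-out knowns score higher than candidates.
    """
    known = corpus.known
    if len(known) < 2:
        raise ValueError("leave-one-out needs at least two known entities")
    vocab = build_vocabulary(corpus, vocab_size)
    vectors = tfidf_vectors(corpus, vocab)
    centroids = entity_centroids(vectors, corpus)
    graph = similarity_graph(centroids)

    full = diffusion_rank(graph, known, alpha=alpha)
    negative_scores = {c: full.scores[c] for c in corpus.candidates}

    holdout_scores: dict[str, float] = {}
    holdout_ranks: dict[str, int] = {}
    for k in known:
        reduced = [e for e in known if e != k]
        ranked = diffusion_rank(graph, reduced, alpha=alpha)
        holdout_scores[k] = ranked.scores[k]
        holdout_ranks[k] = ranked.rank_of(k)

    pos = np.array([holdout_scores[k] for k in known])
    neg = np.array([negative_scores[c] for c in corpus.candidates])
    sl = stats.ScoredLabels(
        scores=np.concatenate([pos, neg]),
        labels=np.concatenate([np.ones(pos.size), np.zeros(neg.size)]),
    )
    roc_points, auc = stats.roc_auc(sl)
    pr_points, ap = stats.precision_recall(sl)
    p = stats.wilcoxon_ranksum_one_tailed(pos, neg)
    return LooValidation(
        roc_points=roc_points,
        auc=auc,
        pr_points=pr_points,
        average_precision=ap,
        ranksum_p=p,
        holdout_ranks=holdout_ranks,
        holdout_scores=holdout_scores,
        negative_scores=negative_scores,
    )
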