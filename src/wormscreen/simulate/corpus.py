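"""Topic-structured synthetic literature corpora.

The vocabulary is split into a small block of topic terms and a larger
block of background terms, each with a Zipf-like frequency profile.
Known entities (and "planted" positive candidates) draw their document
word counts from a mixture ``separation * topic + (1 - separation) *
background``; all other candidates draw from the background alone. At
``topic_separation = 1`` knowns and candidates use disjoint term blocks,
so literature similarity separates them perfectly; at 0 every entity is
exchangeable. Documents are explicit token streams (no natural-language
generation) meant for whitespace tokenisation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ranking import Corpus


@dataclass
class CorpusSimConfig:
    """Known/candidate corpus design, scaled like a drug-repurposing
    screen (15 knowns against several hundred candidates at full size)."""

    n_known: int = 15
    n_candidates: int = 60
    docs_per_entity: int = 5
    vocab_size: int = 200
    topic_separation: float = 0.8
    n_planted_positives: int = 0
    doc_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if self.n_planted_positives > self.n_candidates:
            raise ValueError("n_planted_positives must not exceed n_candidates")
        if not 0.0 <= self.topic_separation <= 1.0:
            raise ValueError("topic_separation must be in [0, 1]")
        if min(self.n_known, self.n_candidates, self.docs_per_entity, self.doc_length) < 1:
            raise ValueError("counts must be positive")


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def simulate_corpus(config: CorpusSimConfig) -> Corpus:
    """Generate a corpus with latent topical structure.

    Entities are named ``known_00`` ... / ``cand_000`` ...; the first
    ``n_planted_positives`` candidates share the known topic. Returns a
    :class:`~wormscreen.ranking.Corpus`; which candidates were planted is
    recoverable from the names (``cand_000`` ... are the planted ones).
    """
    rng = np.random.default_rng(config.seed)
    vocab = np.array([f"w{i:05d}" for i in range(config.vocab_size)])
    n_topic = max(5, config.vocab_size // 10)
    topic_terms = np.arange(n_topic)
    background_terms = np.arange(n_topic, config.vocab_size)

    topic_dist = np.zeros(config.vocab_size)
    topic_dist[topic_terms] = _zipf_weights(n_topic)
    background_dist = np.zeros(config.vocab_size)
    background_dist[background_terms] = _zipf_weights(background_terms.size)

    s = config.topic_separation
    on_topic = s * topic_dist + (1.0 - s) * background_dist

    documents: dict[str, list[str]] = {}
    entity_map: dict[str, set[str]] = {}
    roles: dict[str, str] = {}

    def add_entity(name: str, role: str, dist: np.ndarray) -> None:
        doc_ids = set()
        for d in range(config.docs_per_entity):
            doc_id = f"{name}_doc{d:02d}"
            counts = rng.multinomial(config.doc_length, dist)
            tokens: list[str] = []
            for term_index in np.nonzero(counts)[0]:
                tokens.extend([vocab[term_index]] * counts[term_index])
            documents[doc_id] = tokens
            doc_ids.add(doc_id)
        entity_map[name] = doc_ids
        roles[name] = role

    for i in range(config.n_known):
        add_entity(f"known_{i:02d}", "known", on_topic)
    for i in range(config.n_candidates):
        dist = on_topic if i < config.n_planted_positives else background_dist
        add_entity(f"cand_{i:03d}", "candidate", dist)

    return Corpus(documents=documents, entity_map=entity_map, roles=roles)
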