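"""Baseline protein function predictors.

Four reference predictors against which hosted methods are compared:

* **naive** — every target receives every term, scored by the term's relative
  frequency among annotated training proteins (protein-independent).
* **goa_nonexp** — a target's non-experimental annotations at t0 (e.g. IEA)
  are predicted with score 1.0: how well do computational annotations foretell
  future experimental ones?
* **blast** — annotations transferred from sequence-similar training proteins,
  scored by the highest identity among annotated hits.
* **embedding** — the same transfer with embedding-space cosine similarity in
  place of sequence identity.

All baselines emit scores in (0, 1]; zero-score pairs are never emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .benchmark_builder import TimePoint
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionRecord:
    protein: str
    term: str
    score: float


@dataclass
class PredictionSet:
    """A scored protein-term prediction list from one method."""

    method_label: str
    records: list[PredictionRecord] = field(default_factory=list)
    propagated: bool = False

    def by_protein(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for r in self.records:
            out.setdefault(r.protein, {})[r.term] = r.score
        return out

    def write_tsv(self, path) -> None:
        """CAFA submission dialect: protein<TAB>term<TAB>score, 2+ decimals."""
        with open(path, "w") as fh:
            for r in sorted(self.records, key=lambda r: (r.protein, r.term)):
                fh.write(f"{r.protein}\t{r.term}\t{r.score:.6f}\n")

    @classmethod
    def read_tsv(cls, path, method_label: str) -> "PredictionSet":
        recs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path} line {lineno}: expected 3 columns")
                protein, term, score = fields
                recs.append(PredictionRecord(protein, term, float(score)))
        return cls(method_label=method_label, records=recs)


@dataclass
class SimilarityHitTable:
    """(query, subject) -> identity fraction in [0, 1], max-merged over duplicates."""

    hits: dict[tuple[str, str], float]

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, float]]) -> "SimilarityHitTable":
        hits: dict[tuple[str, str], float] = {}
        for query, subject, identity in rows:
            if not (0.0 <= identity <= 1.0):
                raise ValueError(
                    f"identity {identity} for ({query}, {subject}) outside [0, 1]"
                )
            key = (query, subject)
            hits[key] = max(hits.get(key, 0.0), identity)
        return cls(hits=hits)

    @classmethod
    def read_blast_tabular(cls, path) -> "SimilarityHitTable":
        """Ingest BLAST ``-outfmt 6`` output (qseqid, sseqid, pident, ...)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["query", "subject", "pident"])
        return cls.from_rows(
            (q, s, p / 100.0) for q, s, p in df.itertuples(index=False)
        )


@dataclass
class EmbeddingMatrix:
    """accession -> fixed-dimension real vector; no zero-norm vectors."""

    vectors: dict[str, np.ndarray]
    dimension: int

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[float]]) -> "EmbeddingMatrix":
        vectors = {acc: np.asarray(v, dtype=float) for acc, v in mapping.items()}
        dims = {v.shape for v in vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"embedding vectors have mixed dimensions: {dims}")
        for acc, v in vectors.items():
            if not np.linalg.norm(v) > 0:
                raise ValueError(f"zero-norm embedding for {acc!r}")
        dim = next(iter(dims))[0] if vectors else 0
        return cls(vectors=vectors, dimension=dim)

    @classmethod
    def read_tsv(cls, path) -> "EmbeddingMatrix":
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls.from_mapping(
            {str(acc): row.to_numpy(dtype=float) for acc, row in df.iterrows()}
        )


def _root_filtered(terms: Iterable[str], graph: OntologyGraph | None,
                   exclude_roots: bool) -> set[str]:
    terms = set(terms)
    if exclude_roots and graph is not None:
        terms -= set(graph.roots.values())
    return terms


def naive_predict(
    frequencies: Mapping[str, Mapping[str, float]],
    targets: Iterable[str],
    graph: OntologyGraph | None = None,
    exclude_roots: bool = True,
) -> PredictionSet:
    """Frequency predictor: every target gets every term at its training frequency.

    *frequencies* maps aspect -> {term: frequency} as produced by
    :func:`funcbench.annotation_io.term_frequencies`.
    """
    records = []
    term_scores = sorted(
        (term, freq)
        for per_aspect in frequencies.values()
        for term, freq in per_aspect.items()
        if freq > 0
    )
    roots = set(graph.roots.values()) if (graph is not None and exclude_roots) else set()
    for target in sorted(set(targets)):
        for term, freq in term_scores:
            if term in roots:
                continue
            records.append(PredictionRecord(target, term, min(freq, 1.0)))
    return PredictionSet(method_label="naive", records=records, propagated=True)


def goa_nonexp_predict(
    tp0: TimePoint,
    targets: Iterable[str],
    graph: OntologyGraph | None = None,
    exclude_roots: bool = True,
) -> PredictionSet:
    """Predict each target's propagated non-experimental t0 annotations at 1.0.

    The non-experimental set is the propagated all-evidence set minus the
    propagated experimental set.
    """
    targets = set(targets)
    records = []
    for (protein, aspect), all_terms in sorted(tp0.snapshot_all.propagated.items()):
        if protein not in targets:
            continue
        exp_terms = tp0.snapshot_exp.propagated.get((protein, aspect), set())
        nonexp = _root_filtered(all_terms - exp_terms, graph, exclude_roots)
        for term in sorted(nonexp):
            records.append(PredictionRecord(protein, term, 1.0))
    return PredictionSet(method_label="goa_nonexp", records=records, propagated=True)


def _transfer_from_neighbors(
    neighbor_sims: Mapping[str, list[tuple[str, float]]],
    tp_train: TimePoint,
    graph: OntologyGraph | None,
    exclude_roots: bool,
    method_label: str,
) -> PredictionSet:
    """Max-rule annotation transfer shared by the BLAST and embedding baselines.

    score(target, term) = max similarity over neighbors whose propagated
    experimental set contains the term.  Because annotation sets are ancestry
    closed, the max rule makes ancestor scores automatically >= descendant
    scores (no re-propagation needed).
    """
    roots = set(graph.roots.values()) if (graph is not None and exclude_roots) else set()
    annotations: dict[str, set[str]] = {}
    for (protein, _aspect), terms in tp_train.snapshot_exp.propagated.items():
        annotations.setdefault(protein, set()).update(terms - roots)
    records = []
    for target in sorted(neighbor_sims):
        scores: dict[str, float] = {}
        for subject, sim in neighbor_sims[target]:
            if sim <= 0.0:
                continue
            for term in annotations.get(subject, ()):
                scores[term] = max(scores.get(term, 0.0), sim)
        for term in sorted(scores):
            records.append(PredictionRecord(target, term, scores[term]))
    return PredictionSet(method_label=method_label, records=records, propagated=True)


def blast_transfer(
    hits: SimilarityHitTable,
    tp_train: TimePoint,
    targets: Iterable[str],
    graph: OntologyGraph | None = None,
    exclude_roots: bool = True,
) -> PredictionSet:
    """Homology transfer: per-term max identity over annotated training hits."""
    targets = set(targets)
    neighbor_sims: dict[str, list[tuple[str, float]]] = {}
    for (query, subject), identity in hits.hits.items():
        if query not in targets or subject not in tp_train.training_set:
            continue
        neighbor_sims.setdefault(query, []).append((subject, identity))
    return _transfer_from_neighbors(
        neighbor_sims, tp_train, graph, exclude_roots, method_label="blast"
    )


def embedding_transfer(
    embeddings: EmbeddingMatrix,
    tp_train: TimePoint,
    targets: Iterable[str],
    top_k: int = 50,
    graph: OntologyGraph | None = None,
    exclude_roots: bool = True,
) -> PredictionSet:
    """Embedding-space transfer: cosine similarity (clipped to [0,1]), top-k refs.

    Training proteins without an annotation contribute nothing; targets without
    an embedding are skipped with a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be a positive integer")
    refs = sorted(
        p for p in tp_train.training_set
        if p in embeddings.vectors
    )
    if not refs:
        raise ValueError("no training protein has an embedding")
    ref_matrix = np.stack([embeddings.vectors[p] for p in refs])
    ref_norms = np.linalg.norm(ref_matrix, axis=1)
    neighbor_sims: dict[str, list[tuple[str, float]]] = {}
    for target in sorted(set(targets)):
        vec = embeddings.vectors.get(target)
        if vec is None:
            logger.warning("target %s has no embedding; skipped", target)
            continue
        sims = ref_matrix @ vec / (ref_norms * np.linalg.norm(vec))
        sims = np.clip(sims, 0.0, 1.0)
        order = np.argsort(-sims, kind="stable")[:top_k]
        neighbor_sims[target] = [(refs[i], float(sims[i])) for i in order]
    return _transfer_from_neighbors(
        neighbor_sims, tp_train, graph, exclude_roots, method_label="embedding"
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity fraction between two sequences.

    Needleman-Wunsch with match +1, mismatch 0, linear gap 0; identity is the
    number of matched columns divided by the alignment length.  Ties in the
    traceback are broken deterministically: diagonal, then up (gap in b), then
    left (gap in a).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    # DP over match counts; gaps and mismatches cost nothing.
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    eq = (np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
          == np.frombuffer(b.encode(), dtype=np.uint8)[None, :])
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + eq[i - 1]
        np.maximum(diag, score[i - 1, 1:], out=score[i, 1:])
        # a gap-in-b (left) move is free, so it is a running max along the row
        np.maximum.accumulate(score[i], out=score[i])
    # traceback: prefer diagonal, then up, then left
    i, j = n, m
    matches = 0
    length = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + eq[i - 1, j - 1]:
            matches += int(eq[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j]:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length
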