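"""Synthetic data generation: ontologies, paired releases, predictions.

Everything the benchmarking pipeline consumes can be generated here without
any download: a random three-aspect ontology (OBO), a pair of annotation
releases in which annotations only accumulate (GAF 2.2 + FASTA, with optional
sequence mutations between releases), similarity hit tables and k-mer
embeddings, and prediction files of controllable quality.

Every generator is a pure function of its configuration (including the seed):
identical inputs produce byte-identical output files.

The accumulation model emulates how experimental GO annotations accrue between
database releases: a protein may be pre-annotated at t0, and newly gained terms
appear with experimental evidence at t1.  Gains are placed in aspects where the
protein had no prior experimental annotation (the no-knowledge benchmark
scenario), so the accumulated ground truth for a protein is a complete
ancestry-closed set and a perfect predictor is exactly recoverable.  A fraction
of gains is pre-announced at t0 with the computational evidence code IEA, which
is what the non-experimental annotation baseline exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .baselines import pairwise_identity
from .ontology import (
    ASPECTS,
    CANONICAL_ROOTS,
    OntologyGraph,
    Term,
    propagate_terms,
    write_obo,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

EXPERIMENTAL_CODES = ("IDA", "IMP", "IGI", "IEP", "EXP", "IPI")

_ASPECT_LETTER = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


@dataclass
class FixtureConfig:
    """Knobs for the synthetic study conditions.

    Defaults give a small but structured world: three 50-term aspects, 100
    proteins, moderate annotation density — everything runs in seconds.
    """

    n_terms: int = 50            # terms per aspect, root included
    branching: int = 2           # max parents per non-root term
    n_top: int = 10              # root children (top-level branch heads) per aspect
    n_proteins: int = 100
    p_annot: float = 0.6         # P(protein experimentally annotated at t0)
    gain_rate: float = 2.0       # expected newly gained terms per protein per window
    nonexp_rate: float = 0.3     # P(gained term pre-announced as IEA at t0)
    bg_nonexp_rate: float = 0.3  # P(protein carries an unrelated IEA annotation at t0)
    mut_rate: float = 0.1        # P(one residue substitution between releases)
    seq_length: int = 60
    q: float = 0.0               # corrupted fraction for degraded predictors
    seed: int = 0
    t0_id: str = "2025-09"
    t1_id: str = "2026-03"

    def __post_init__(self):
        for name in ("p_annot", "nonexp_rate", "bg_nonexp_rate", "mut_rate", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.n_terms, self.n_proteins, self.seq_length, self.branching) < 1:
            raise ValueError("counts must be positive")


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_ontology(config: FixtureConfig, path=None) -> OntologyGraph:
    """Generate a random three-aspect DAG and optionally write it as OBO.

    Each aspect mimics the Gene Ontology's shape in miniature: the root fans
    out to ``n_top`` top-level branch heads, and every further term attaches to
    1..branching parents drawn from a single branch (diamonds form within a
    branch, never across branches).  Distinct branches therefore share only the
    aspect root, so the ancestor closures of unrelated terms are nearly
    disjoint — the property that makes random false predictions score poorly.
    Parents always precede children in generation order, guaranteeing
    acyclicity; each edge is is_a or, with probability 0.2, part_of.
    """
    rng = _rng(config, 1)
    terms: dict[str, Term] = {}
    import networkx as nx

    graph = nx.DiGraph()
    counter = 1
    for aspect in ASPECTS:
        root = CANONICAL_ROOTS[aspect]
        terms[root] = Term(id=root, name=f"{aspect} root", aspect=aspect)
        graph.add_node(root)
        branches: list[list[str]] = []
        for _ in range(config.n_terms - 1):
            tid = f"GO:{7000000 + counter:07d}"
            counter += 1
            terms[tid] = Term(id=tid, name=f"synthetic term {counter}", aspect=aspect)
            graph.add_node(tid)
            if len(branches) < config.n_top:
                graph.add_edge(tid, root, relation="is_a")
                branches.append([tid])
            else:
                branch = branches[int(rng.integers(len(branches)))]
                n_parents = min(int(rng.integers(1, config.branching + 1)),
                                len(branch))
                parents = rng.choice(len(branch), size=n_parents, replace=False)
                for pi in sorted(parents):
                    relation = "part_of" if rng.random() < 0.2 else "is_a"
                    graph.add_edge(tid, branch[pi], relation=relation)
                branch.append(tid)
    roots = {aspect: CANONICAL_ROOTS[aspect] for aspect in ASPECTS}
    onto = OntologyGraph(terms=terms, graph=graph, roots=roots)
    if path is not None:
        write_obo(onto, path)
    return onto


def _gaf_line(protein: str, term: str, evidence: str, aspect: str, date: str) -> str:
    fields = [
        "UniProtKB", protein, protein, "", term, "GO_REF:0000001", evidence,
        "", _ASPECT_LETTER[aspect], f"protein {protein}", protein, "protein",
        "taxon:9606", date, "SyntheticGen", "", "",
    ]
    return "\t".join(fields)


def _write_gaf(path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for line in lines:
            fh.write(line + "\n")


def _write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for acc in sorted(sequences):
            fh.write(f">sp|{acc}|{acc}_SYNTH\n{sequences[acc]}\n")


def make_release_pair(config: FixtureConfig, graph: OntologyGraph, out_dir) -> dict:
    """Write paired GAF/FASTA releases (t0, t1) plus a bookkeeping manifest.

    t1 annotation lines are a superset of t0 lines (accumulation-only model).
    Returns a dict with the written paths under keys ``gaf_t0``, ``gaf_t1``,
    ``fasta_t0``, ``fasta_t1``, ``manifest``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 2)
    date0 = config.t0_id.replace("-", "") + "01"
    date1 = config.t1_id.replace("-", "") + "01"
    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    nonroot: dict[str, list[str]] = {
        aspect: sorted(
            t.id for t in graph.terms.values()
            if t.aspect == aspect and not graph.is_root(t.id)
        )
        for aspect in ASPECTS
    }
    # leaves: active terms with no children (no incoming child->parent edge)
    leaves: dict[str, list[str]] = {
        aspect: [t for t in nonroot[aspect] if graph.graph.in_degree(t) == 0]
        for aspect in ASPECTS
    }

    # --- sequences -------------------------------------------------------
    seqs_t0 = {
        p: "".join(rng.choice(list(AMINO_ACIDS), size=config.seq_length))
        for p in proteins
    }
    seqs_t1 = dict(seqs_t0)
    mutated: list[str] = []
    for p in proteins:
        if rng.random() < config.mut_rate:
            pos = int(rng.integers(config.seq_length))
            old = seqs_t0[p][pos]
            new = rng.choice([a for a in AMINO_ACIDS if a != old])
            seqs_t1[p] = seqs_t0[p][:pos] + new + seqs_t0[p][pos + 1:]
            mutated.append(p)

    # --- t0 annotations --------------------------------------------------
    lines_t0: list[str] = []
    manifest_proteins: dict[str, dict] = {}
    for p in proteins:
        entry = {
            "t0_exp": {}, "t0_nonexp": {}, "gains": {}, "mutated": p in mutated,
        }
        annotated_aspects: list[str] = []
        if rng.random() < config.p_annot:
            k = int(rng.integers(1, 3))
            annotated_aspects = sorted(
                rng.choice(ASPECTS, size=min(k, len(ASPECTS)), replace=False)
            )
            for aspect in annotated_aspects:
                n_terms = int(rng.integers(1, 3))
                picked = sorted(
                    rng.choice(nonroot[aspect], size=n_terms, replace=False)
                )
                entry["t0_exp"][aspect] = picked
                for term in picked:
                    code = str(rng.choice(EXPERIMENTAL_CODES))
                    lines_t0.append(_gaf_line(p, term, code, aspect, date0))
        if rng.random() < config.bg_nonexp_rate:
            aspect = str(rng.choice(ASPECTS))
            term = str(rng.choice(nonroot[aspect]))
            entry["t0_nonexp"].setdefault(aspect, [])
            if term not in entry["t0_nonexp"][aspect]:
                entry["t0_nonexp"][aspect].append(term)
            lines_t0.append(_gaf_line(p, term, "IEA", aspect, date0))

        # --- gains: new experimental leaf terms at t1, in aspects with no
        # prior experimental annotation (no-knowledge scenario) ------------
        free_aspects = [a for a in ASPECTS if a not in entry["t0_exp"]]
        n_gains = int(rng.poisson(config.gain_rate)) if free_aspects else 0
        for _ in range(n_gains):
            aspect = str(rng.choice(free_aspects))
            term = str(rng.choice(leaves[aspect]))
            entry["gains"].setdefault(aspect, [])
            if term in entry["gains"][aspect]:
                continue
            entry["gains"][aspect].append(term)
            if rng.random() < config.nonexp_rate:
                entry["t0_nonexp"].setdefault(aspect, [])
                if term not in entry["t0_nonexp"][aspect]:
                    entry["t0_nonexp"][aspect].append(term)
                lines_t0.append(_gaf_line(p, term, "IEA", aspect, date0))
        for aspect in entry["gains"]:
            entry["gains"][aspect].sort()
        manifest_proteins[p] = entry

    # --- t1 = t0 plus the gained experimental lines ----------------------
    lines_t1 = list(lines_t0)
    gain_rng = _rng(config, 3)
    for p in proteins:
        for aspect, terms in sorted(manifest_proteins[p]["gains"].items()):
            for term in terms:
                code = str(gain_rng.choice(EXPERIMENTAL_CODES))
                lines_t1.append(_gaf_line(p, term, code, aspect, date1))

    paths = {
        "gaf_t0": out / f"goa_{config.t0_id}.gaf",
        "gaf_t1": out / f"goa_{config.t1_id}.gaf",
        "fasta_t0": out / f"sequences_{config.t0_id}.fasta",
        "fasta_t1": out / f"sequences_{config.t1_id}.fasta",
        "manifest": out / "manifest.json",
    }
    _write_gaf(paths["gaf_t0"], lines_t0)
    _write_gaf(paths["gaf_t1"], lines_t1)
    _write_fasta(paths["fasta_t0"], seqs_t0)
    _write_fasta(paths["fasta_t1"], seqs_t1)
    manifest = {
        "t0_id": config.t0_id,
        "t1_id": config.t1_id,
        "proteins": manifest_proteins,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def manifest_ground_truth(
    manifest: dict, graph: OntologyGraph
) -> dict[str, dict[str, set[str]]]:
    """Reconstruct the expected window ground truth from the manifest.

    Per aspect: protein -> propagate(gains) - propagate(t0 experimental) -
    root, for non-mutated proteins only.  This is an independent route to the
    same quantity the benchmark builder computes from the GAF/FASTA pair.
    """
    roots = set(graph.roots.values())
    out: dict[str, dict[str, set[str]]] = {a: {} for a in ASPECTS}
    for protein, entry in manifest["proteins"].items():
        if entry["mutated"]:
            continue
        for aspect, gains in entry["gains"].items():
            t0_exp = set(entry["t0_exp"].get(aspect, []))
            gt = (
                propagate_terms(graph, gains)
                - propagate_terms(graph, t0_exp)
                - roots
            )
            if gt:
                out[aspect][protein] = gt
    return out


def make_predictions(
    manifest: dict,
    graph: OntologyGraph,
    q: float,
    seed: int,
    path,
) -> str:
    """Write a prediction TSV of controllable quality for the manifest's window.

    For each benchmark protein the gained leaf terms are emitted with scores
    drawn uniformly from [0.71, 1.00] at 0.01 resolution; with probability *q*
    a true leaf is swapped for a random false term of the same aspect scored in
    the same band (false = outside the protein's ground-truth closure).
    Evaluation propagates scores up the DAG, so q=0 reconstructs the ground
    truth exactly (a perfect predictor) while q=1 is fully corrupted.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q={q} outside [0, 1]")
    rng = np.random.default_rng([seed, 17])
    gt = manifest_ground_truth(manifest, graph)
    lines = []
    for aspect in ASPECTS:
        aspect_terms = sorted(
            t.id for t in graph.terms.values()
            if t.aspect == aspect and not graph.is_root(t.id)
        )
        for protein in sorted(gt[aspect]):
            true_terms = gt[aspect][protein]
            entry = manifest["proteins"][protein]
            scores: dict[str, float] = {}
            for term in sorted(entry["gains"].get(aspect, [])):
                emitted = term
                if rng.random() < q:
                    decoys = [t for t in aspect_terms if t not in true_terms]
                    if decoys:
                        emitted = str(rng.choice(decoys))
                score = round(float(rng.integers(71, 101)) / 100.0, 2)
                scores[emitted] = max(scores.get(emitted, 0.0), score)
            for term in sorted(scores):
                lines.append(f"{protein}\t{term}\t{scores[term]:.2f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return str(path)


def make_similarity_and_embeddings(
    fasta_sequences: dict[str, str],
    training_set: set[str],
    config: FixtureConfig,
    out_dir,
    identity_floor: float = 0.3,
) -> dict:
    """Write a similarity hit table and a k-mer embedding TSV for the fixture.

    The hit table holds global-alignment identities for every target x training
    pair at or above *identity_floor* (BLAST tabular dialect, pident in
    percent).  Embeddings are unit-normalised dipeptide (k=2) count vectors, so
    embedding cosine similarity correlates with sequence identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits_path = out / "similarity_hits.tsv"
    emb_path = out / "embeddings.tsv"
    targets = sorted(fasta_sequences)
    training = sorted(training_set & fasta_sequences.keys())
    with open(hits_path, "w") as fh:
        for query in targets:
            for subject in training:
                if subject == query:
                    continue
                ident = pairwise_identity(fasta_sequences[query],
                                          fasta_sequences[subject])
                if ident >= identity_floor:
                    fh.write(
                        f"{query}\t{subject}\t{ident * 100:.2f}\t0\t0\t0\t"
                        f"1\t{config.seq_length}\t1\t{config.seq_length}\t"
                        f"1e-10\t100.0\n"
                    )
    kmers = {a + b: i for i, (a, b) in enumerate(
        (x, y) for x in AMINO_ACIDS for y in AMINO_ACIDS
    )}
    with open(emb_path, "w") as fh:
        for acc in targets:
            seq = fasta_sequences[acc]
            vec = np.zeros(len(kmers))
            for i in range(len(seq) - 1):
                idx = kmers.get(seq[i:i + 2])
                if idx is not None:
                    vec[idx] += 1.0
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
            fh.write(acc + "\t" + "\t".join(f"{v:.6f}" for v in vec) + "\n")
    return {"hits": str(hits_path), "embeddings": str(emb_path)}
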