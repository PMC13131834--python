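"""Time-point and time-window construction for time-delayed benchmarking.

A *time point* bundles one data release: its annotation snapshots (all evidence
and experimental-only), its sequences, and the derived training and test sets.
A *time window* (t0, t1) pairs two time points: the benchmark ground truth is
the set of experimentally supported terms that accumulated between the two
releases for proteins whose sequence did not change — so predictions made at t0
remain valid at t1 and the evaluation rewards only genuinely new knowledge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

from .annotation_io import (
    DEFAULT_EXPERIMENTAL_CODES,
    AnnotationSnapshot,
    SequenceSet,
    build_snapshot,
    filter_experimental,
    parse_fasta,
    parse_gaf,
    write_snapshot_tsvs,
)
from .ontology import ASPECTS, OntologyGraph


@dataclass
class TimePoint:
    """One release bundle: snapshots, sequences, training and test sets.

    The test set is every accession in the release FASTA (the reviewed-sequence
    universe); the training set is every protein holding at least one
    experimental annotation in the release.
    """

    release_id: str
    snapshot_all: AnnotationSnapshot
    snapshot_exp: AnnotationSnapshot
    sequences: SequenceSet
    test_set: set[str]
    training_set: set[str]


@dataclass
class GroundTruth:
    """Per aspect: protein -> non-empty set of newly accumulated terms (propagated)."""

    by_aspect: dict[str, dict[str, set[str]]]

    def n_proteins(self, aspect: str) -> int:
        return len(self.by_aspect.get(aspect, {}))


@dataclass
class TimeWindow:
    t0: str
    t1: str
    common_test_set: set[str]
    ground_truth: GroundTruth
    status: str = "pending"

    @property
    def label(self) -> str:
        return f"{self.t0}--{self.t1}"


@dataclass
class Catalog:
    """Registry of benchmark windows and their readiness status."""

    entries: dict[str, dict] = field(default_factory=dict)

    def ready(self) -> list[str]:
        return sorted(k for k, v in self.entries.items() if v["status"] == "ready")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": self.entries}, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "Catalog":
        p = Path(path)
        if not p.exists():
            return cls()
        with open(p) as fh:
            return cls(entries=json.load(fh)["entries"])


def build_timepoint(
    gaf_path,
    fasta_path,
    graph: OntologyGraph,
    release_id: str,
    evidence_codes: Iterable[str] = DEFAULT_EXPERIMENTAL_CODES,
    out_dir=None,
) -> TimePoint:
    """Construct a complete release bundle from a GAF and a FASTA.

    If *out_dir* is given, the derived sets are written there as a bundle
    directory: snapshot TSVs, training/test accession lists and the sequences.
    """
    records = parse_gaf(gaf_path, graph)
    sequences = parse_fasta(fasta_path, release_id)
    if not sequences.sequences:
        raise ValueError(f"{fasta_path}: empty FASTA, no test set can be built")
    snapshot_all = build_snapshot(records, graph, release_id)
    exp_records = filter_experimental(records, evidence_codes)
    snapshot_exp = build_snapshot(exp_records, graph, release_id)
    tp = TimePoint(
        release_id=release_id,
        snapshot_all=snapshot_all,
        snapshot_exp=snapshot_exp,
        sequences=sequences,
        test_set=set(sequences.sequences),
        training_set={r.protein for r in exp_records},
    )
    if out_dir is not None:
        write_timepoint_bundle(tp, out_dir)
    return tp


def write_timepoint_bundle(tp: TimePoint, out_dir) -> Path:
    """Write the bundle directory layout for one release."""
    out = Path(out_dir) / tp.release_id
    out.mkdir(parents=True, exist_ok=True)
    write_snapshot_tsvs(
        tp.snapshot_all, out / "snapshot_direct.tsv", out / "snapshot_propagated.tsv"
    )
    (out / "training_set.txt").write_text(
        "".join(f"{p}\n" for p in sorted(tp.training_set))
    )
    (out / "test_set.txt").write_text(
        "".join(f"{p}\n" for p in sorted(tp.test_set))
    )
    with open(out / "sequences.fasta", "w") as fh:
        for acc in sorted(tp.sequences.sequences):
            fh.write(f">{acc}\n{tp.sequences.sequences[acc]}\n")
    return out


def common_test_set(tp0: TimePoint, tp1: TimePoint) -> set[str]:
    """Accessions whose amino-acid sequence is exactly equal in both releases."""
    s0, s1 = tp0.sequences.sequences, tp1.sequences.sequences
    return {
        acc
        for acc in s0.keys() & s1.keys()
        if s0[acc].upper() == s1[acc].upper()
    }


def build_ground_truth(
    tp0: TimePoint,
    tp1: TimePoint,
    graph: OntologyGraph,
    exclude_roots: bool = True,
) -> TimeWindow:
    """Build the (t0, t1) window: common test set plus accumulated ground truth.

    For each common-test-set protein and each aspect, the ground truth is the
    propagated experimental annotation set at t1 minus the propagated
    experimental set at t0 (aspect roots removed when *exclude_roots*).
    Proteins with an empty difference in an aspect are omitted from that
    aspect's map.
    """
    if tp0.release_id == tp1.release_id:
        raise ValueError("t0 and t1 must be distinct releases")
    common = common_test_set(tp0, tp1)
    roots = set(graph.roots.values())
    by_aspect: dict[str, dict[str, set[str]]] = {a: {} for a in ASPECTS}
    for (protein, aspect), t1_terms in tp1.snapshot_exp.propagated.items():
        if protein not in common:
            continue
        t0_terms = tp0.snapshot_exp.propagated.get((protein, aspect), set())
        gained = t1_terms - t0_terms
        if exclude_roots:
            gained -= roots
        if gained:
            by_aspect[aspect][protein] = gained
    return TimeWindow(
        t0=tp0.release_id,
        t1=tp1.release_id,
        common_test_set=common,
        ground_truth=GroundTruth(by_aspect=by_aspect),
    )


def update_catalog(
    catalog: Catalog, window: TimeWindow, status: str, stamp: str | None = None
) -> Catalog:
    """Upsert a window entry under its ``t0--t1`` label. Idempotent.

    *stamp* defaults to today's UTC date; pass an explicit value (e.g. the t1
    release id) where byte-identical reruns are required.
    """
    if status not in ("pending", "ready"):
        raise ValueError(f"unknown status {status!r}; expected 'pending' or 'ready'")
    window.status = status
    catalog.entries[window.label] = {
        "status": status,
        "n_benchmark_proteins": {
            a: window.ground_truth.n_proteins(a) for a in ASPECTS
        },
        "created": stamp or datetime.now(timezone.utc).strftime("%Y-%m-%d"),
    }
    return catalog


def write_ground_truth_tsvs(window: TimeWindow, out_dir) -> Path:
    """Write the per-aspect (protein, term) ground-truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for aspect, prot_map in window.ground_truth.by_aspect.items():
        if not prot_map:
            continue
        with open(out / f"ground_truth_{aspect}.tsv", "w") as fh:
            for protein in sorted(prot_map):
                for term in sorted(prot_map[protein]):
                    fh.write(f"{protein}\t{term}\n")
    return out
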