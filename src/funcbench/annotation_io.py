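"""GAF / FASTA ingestion and per-release annotation snapshots.

A release of UniProt-GOA is read into :class:`AnnotationRecord` rows, filtered
by evidence class, and aggregated into an :class:`AnnotationSnapshot` holding
both the direct protein->term maps and their true-path closures.  Sequences for
the same release are read into a :class:`SequenceSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.UniProt import GOA

from .ontology import OntologyGraph, propagate_terms

logger = logging.getLogger(__name__)

#: Evidence codes treated as experimental by default.  Covers the classic
#: experimental codes (EXP family), their high-throughput variants (HTP family)
#: and the curator codes TAS/IC, following CAFA practice.  Always overridable.
DEFAULT_EXPERIMENTAL_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
     "HTP", "HDA", "HMP", "HGI", "HEP", "TAS", "IC"}
)

#: GAF aspect column letter -> ontology namespace
ASPECT_LETTER = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}

# Amino-acid alphabet including ambiguity codes and the rare residues U/O.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO*")


class GafFormatError(ValueError):
    """Malformed GAF input (missing version header, aspect mismatch...)."""


class FastaFormatError(ValueError):
    """Malformed FASTA input (duplicate accession, bad residues...)."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF body line: a protein annotated with one GO term."""

    protein: str
    term: str
    evidence: str
    qualifier: tuple[str, ...]
    aspect: str
    date: str


class GafRecords(list):
    """Parsed GAF records plus counters for the lines that were screened out."""

    def __init__(self, records: Iterable[AnnotationRecord] = ()):
        super().__init__(records)
        self.n_not_excluded = 0
        self.n_obsolete_dropped = 0
        self.n_unknown_term = 0


@dataclass
class AnnotationSnapshot:
    """One release's annotations, before and after true-path propagation.

    ``direct`` and ``propagated`` map (protein, aspect) -> set of term ids;
    proteins with no annotation in an aspect have no entry (no empty sets).
    """

    release_id: str
    records: list[AnnotationRecord]
    direct: dict[tuple[str, str], set[str]]
    propagated: dict[tuple[str, str], set[str]]

    def proteins(self, aspect: str | None = None) -> set[str]:
        return {
            p for (p, a) in self.propagated if aspect is None or a == aspect
        }


@dataclass
class SequenceSet:
    release_id: str
    sequences: dict[str, str]

    def __len__(self) -> int:
        return len(self.sequences)


def parse_gaf(path, graph: OntologyGraph) -> GafRecords:
    """Read a GAF 2.1/2.2 file into :class:`AnnotationRecord` rows.

    Lines carrying a NOT qualifier or referring to an obsolete term are counted
    on the returned collection (``n_not_excluded``, ``n_obsolete_dropped``) and
    excluded; lines whose term is entirely unknown are counted under
    ``n_unknown_term``.  The GAF aspect letter must agree with the ontology's
    namespace for the term.

    Raises
    ------
    GafFormatError
        If the file lacks a ``!gaf-version:`` header or an aspect column
        contradicts the ontology.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("!gaf-version:"):
            raise GafFormatError(f"{path}: missing !gaf-version header line")
        fh.seek(0)
        out = GafRecords()
        for lineno, rec in enumerate(GOA.gafiterator(fh), start=2):
            qualifier = tuple(q for q in rec["Qualifier"] if q)
            term = rec["GO_ID"]
            if "NOT" in qualifier:
                out.n_not_excluded += 1
                continue
            if term in graph.obsolete:
                out.n_obsolete_dropped += 1
                continue
            if term not in graph.terms:
                out.n_unknown_term += 1
                continue
            aspect = ASPECT_LETTER.get(rec["Aspect"])
            if aspect != graph.aspect_of(term):
                raise GafFormatError(
                    f"{path} line {lineno}: aspect column {rec['Aspect']!r} "
                    f"disagrees with ontology aspect {graph.aspect_of(term)!r} "
                    f"for term {term}"
                )
            out.append(
                AnnotationRecord(
                    protein=rec["DB_Object_ID"],
                    term=term,
                    evidence=rec["Evidence"],
                    qualifier=qualifier,
                    aspect=aspect,
                    date=rec["Date"],
                )
            )
    if out.n_not_excluded or out.n_obsolete_dropped or out.n_unknown_term:
        logger.warning(
            "%s: excluded %d NOT-qualified, %d obsolete-term, %d unknown-term lines",
            path, out.n_not_excluded, out.n_obsolete_dropped, out.n_unknown_term,
        )
    return out


def filter_experimental(
    records: Iterable[AnnotationRecord], codes: Iterable[str] = DEFAULT_EXPERIMENTAL_CODES
) -> list[AnnotationRecord]:
    """Keep exactly the records whose evidence code is in *codes* (order kept)."""
    codes = frozenset(codes)
    if not codes:
        raise ValueError("evidence code set must be non-empty")
    return [r for r in records if r.evidence in codes]


def build_snapshot(
    records: Iterable[AnnotationRecord], graph: OntologyGraph, release_id: str
) -> AnnotationSnapshot:
    """Aggregate records into direct and propagated per-(protein, aspect) maps."""
    records = list(records)
    direct: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.term not in graph.terms:
            raise KeyError(f"record term {r.term!r} not active in ontology")
        if graph.aspect_of(r.term) != r.aspect:
            raise GafFormatError(
                f"record for {r.protein}: term {r.term} belongs to aspect "
                f"{graph.aspect_of(r.term)!r}, record says {r.aspect!r}"
            )
        direct.setdefault((r.protein, r.aspect), set()).add(r.term)
    propagated = {
        key: propagate_terms(graph, terms) for key, terms in direct.items()
    }
    return AnnotationSnapshot(
        release_id=release_id, records=records, direct=direct, propagated=propagated
    )


def parse_fasta(path, release_id: str) -> SequenceSet:
    """Read FASTA into accession -> uppercase sequence.

    Accessions are extracted from UniProt-style ``sp|ACC|NAME`` / ``tr|ACC|NAME``
    headers and from bare-accession headers.  Duplicate accessions, empty
    sequences and illegal residue characters are errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            parts = header.split("|")
            if len(parts) < 2 or not parts[1]:
                raise FastaFormatError(f"{path}: cannot extract accession from {header!r}")
            acc = parts[1]
        else:
            acc = header
        if acc in sequences:
            raise FastaFormatError(f"{path}: duplicate accession {acc!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: empty sequence for {acc!r}")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise FastaFormatError(
                f"{path}: illegal residue(s) {sorted(bad)} in {acc!r}"
            )
        sequences[acc] = seq
    return SequenceSet(release_id=release_id, sequences=sequences)


def term_frequencies(snapshot: AnnotationSnapshot, aspect: str) -> dict[str, float]:
    """Relative frequency of each term among the propagated sets of one aspect.

    frequency(t) = #{proteins whose propagated set contains t} / #{proteins with
    any annotation in the aspect}.  The aspect root therefore scores 1.0.
    """
    prot_sets = [
        terms for (p, a), terms in snapshot.propagated.items() if a == aspect
    ]
    if not prot_sets:
        raise ValueError(f"snapshot {snapshot.release_id!r} has no proteins in {aspect!r}")
    n = len(prot_sets)
    counts: dict[str, int] = {}
    for terms in prot_sets:
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: c / n for t, c in counts.items()}


def write_snapshot_tsvs(snapshot: AnnotationSnapshot, direct_path, propagated_path) -> None:
    """Write the direct and propagated maps as (protein, aspect, term) TSVs."""
    for mapping, path in ((snapshot.direct, direct_path),
                          (snapshot.propagated, propagated_path)):
        with open(path, "w") as fh:
            fh.write("protein\taspect\tterm\n")
            for (protein, aspect) in sorted(mapping):
                for term in sorted(mapping[(protein, aspect)]):
                    fh.write(f"{protein}\t{aspect}\t{term}\n")
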