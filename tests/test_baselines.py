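"""The four baseline predictors and their score contracts."""

import math

import numpy as np
import pytest

from funcbench import (
    EmbeddingMatrix,
    PredictionSet,
    SimilarityHitTable,
    blast_transfer,
    build_timepoint,
    embedding_transfer,
    goa_nonexp_predict,
    naive_predict,
    pairwise_identity,
)
from funcbench.annotation_io import term_frequencies
from funcbench.ontology import ancestors

from conftest import A, B, C, write_fasta, write_gaf


@pytest.fixture
def four_protein_tp(tmp_path, chain_graph):
    """4 annotated proteins: C in 2 propagated sets (freq 0.5), B/A in all."""
    gaf = write_gaf(tmp_path / "t.gaf", [
        ("P1", C, "IDA", "F"), ("P2", C, "IDA", "F"),
        ("P3", B, "IDA", "F"), ("P4", B, "IDA", "F"),
    ])
    fasta = write_fasta(tmp_path / "t.fasta",
                        {f"P{i}": "MKVLA" for i in range(1, 7)})
    return build_timepoint(gaf, fasta, chain_graph, "r0")


class TestNaive:
    def test_frequency_scores(self, four_protein_tp, chain_graph):
        freqs = {"molecular_function": term_frequencies(
            four_protein_tp.snapshot_exp, "molecular_function")}
        ps = naive_predict(freqs, {"T1", "T2", "T3"}, chain_graph)
        by_term = {}
        for r in ps.records:
            by_term.setdefault(r.term, []).append((r.protein, r.score))
        assert sorted(s for _, s in by_term[C]) == [0.5, 0.5, 0.5]
        assert all(s == 1.0 for _, s in by_term[B])

    def test_identical_across_targets(self, four_protein_tp, chain_graph):
        freqs = {"molecular_function": term_frequencies(
            four_protein_tp.snapshot_exp, "molecular_function")}
        ps = naive_predict(freqs, {"T1", "T2"}, chain_graph)
        per_target = {}
        for r in ps.records:
            per_target.setdefault(r.protein, {})[r.term] = r.score
        assert per_target["T1"] == per_target["T2"]

    def test_root_not_emitted(self, four_protein_tp, chain_graph):
        freqs = {"molecular_function": term_frequencies(
            four_protein_tp.snapshot_exp, "molecular_function")}
        ps = naive_predict(freqs, {"T1"}, chain_graph)
        assert A not in {r.term for r in ps.records}

    def test_empty_targets(self, four_protein_tp, chain_graph):
        ps = naive_predict({}, set(), chain_graph)
        assert ps.records == []


class TestGoaNonExp:
    def test_iea_closure_scored_one(self, tmp_path, chain_graph):
        gaf = write_gaf(tmp_path / "t.gaf", [("P1", C, "IEA", "F")])
        fasta = write_fasta(tmp_path / "t.fasta", {"P1": "MKVLA"})
        tp = build_timepoint(gaf, fasta, chain_graph, "r0")
        ps = goa_nonexp_predict(tp, {"P1"}, chain_graph)
        assert {(r.term, r.score) for r in ps.records} == {(C, 1.0), (B, 1.0)}

    def test_experimental_only_protein_silent(self, tmp_path, chain_graph):
        gaf = write_gaf(tmp_path / "t.gaf", [("P1", C, "IDA", "F")])
        fasta = write_fasta(tmp_path / "t.fasta", {"P1": "MKVLA"})
        tp = build_timepoint(gaf, fasta, chain_graph, "r0")
        assert goa_nonexp_predict(tp, {"P1"}, chain_graph).records == []

    def test_unannotated_protein_silent(self, four_protein_tp, chain_graph):
        assert goa_nonexp_predict(four_protein_tp, {"P6"}, chain_graph).records == []

    def test_all_scores_exactly_one(self, world):
        ps = goa_nonexp_predict(world.tp0, world.tp0.test_set, world.graph)
        assert ps.records and all(r.score == 1.0 for r in ps.records)


class TestBlastTransfer:
    def _tp(self, tmp_path, chain_graph, rows):
        gaf = write_gaf(tmp_path / "t.gaf", rows)
        fasta = write_fasta(
            tmp_path / "t.fasta",
            {"S1": "MKVLA", "S2": "MKVLA", "Q": "MKVLA"},
        )
        return build_timepoint(gaf, fasta, chain_graph, "r0")

    def test_per_term_max_over_hits(self, tmp_path, chain_graph):
        # S1 (0.9) annotated {C->C,B}; S2 (0.7) annotated {B}
        tp = self._tp(tmp_path, chain_graph,
                      [("S1", C, "IDA", "F"), ("S2", B, "IDA", "F")])
        hits = SimilarityHitTable.from_rows([("Q", "S1", 0.9), ("Q", "S2", 0.7)])
        ps = blast_transfer(hits, tp, {"Q"}, chain_graph)
        scores = {r.term: r.score for r in ps.records}
        assert scores == {C: 0.9, B: 0.9}

    def test_weaker_hit_contributes_unique_terms(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph,
                      [("S1", B, "IDA", "F"), ("S2", C, "IDA", "F")])
        hits = SimilarityHitTable.from_rows([("Q", "S1", 0.9), ("Q", "S2", 0.7)])
        scores = {r.term: r.score for r in blast_transfer(hits, tp, {"Q"}, chain_graph).records}
        assert scores == {B: 0.9, C: 0.7}

    def test_no_hits_no_records(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph, [("S1", C, "IDA", "F")])
        hits = SimilarityHitTable.from_rows([])
        assert blast_transfer(hits, tp, {"Q"}, chain_graph).records == []

    def test_duplicate_rows_max_merged(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph, [("S1", C, "IDA", "F")])
        hits = SimilarityHitTable.from_rows([("Q", "S1", 0.6), ("Q", "S1", 0.8)])
        scores = {r.term: r.score for r in blast_transfer(hits, tp, {"Q"}, chain_graph).records}
        assert scores[C] == 0.8

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimilarityHitTable.from_rows([("Q", "S", 1.2)])

    def test_removing_hit_never_increases_scores(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph,
                      [("S1", C, "IDA", "F"), ("S2", B, "IDA", "F")])
        full = SimilarityHitTable.from_rows([("Q", "S1", 0.9), ("Q", "S2", 0.7)])
        less = SimilarityHitTable.from_rows([("Q", "S2", 0.7)])
        s_full = {r.term: r.score for r in blast_transfer(full, tp, {"Q"}, chain_graph).records}
        s_less = {r.term: r.score for r in blast_transfer(less, tp, {"Q"}, chain_graph).records}
        for term, score in s_less.items():
            assert score <= s_full[term]


class TestEmbeddingTransfer:
    def _tp(self, tmp_path, chain_graph, rows, accs):
        gaf = write_gaf(tmp_path / "t.gaf", rows)
        fasta = write_fasta(tmp_path / "t.fasta", {a: "MKVLA" for a in accs})
        return build_timepoint(gaf, fasta, chain_graph, "r0")

    def test_orthogonal_reference_excluded(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph,
                      [("R1", C, "IDA", "F"), ("R2", B, "IDA", "F")],
                      ["R1", "R2", "Q"])
        emb = EmbeddingMatrix.from_mapping(
            {"Q": [1, 0], "R1": [1, 0], "R2": [0, 1]})
        scores = {r.term: r.score
                  for r in embedding_transfer(emb, tp, {"Q"}, top_k=2, graph=chain_graph).records}
        # R1 cosine 1.0 contributes {C,B}; R2 cosine 0.0 contributes nothing
        assert scores == {C: 1.0, B: 1.0}

    def test_cos45_score(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph,
                      [("R1", C, "IDA", "F"), ("R2", C, "IDA", "F")],
                      ["R1", "R2", "Q"])
        s = 1 / math.sqrt(2)
        emb = EmbeddingMatrix.from_mapping(
            {"Q": [s, s], "R1": [1, 0], "R2": [0, 1]})
        scores = {r.term: r.score
                  for r in embedding_transfer(emb, tp, {"Q"}, top_k=2, graph=chain_graph).records}
        assert scores[C] == pytest.approx(s, abs=1e-12)

    def test_top_k_one(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph,
                      [("R1", C, "IDA", "F"), ("R2", B, "IDA", "F")],
                      ["R1", "R2", "Q"])
        emb = EmbeddingMatrix.from_mapping(
            {"Q": [1, 0], "R1": [1, 0], "R2": [0.5, 0.5]})
        scores = {r.term: r.score
                  for r in embedding_transfer(emb, tp, {"Q"}, top_k=1, graph=chain_graph).records}
        assert scores == {C: 1.0, B: 1.0}    # only the nearest reference used

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            EmbeddingMatrix.from_mapping({"A": [1, 0], "B": [1, 0, 0]})

    def test_target_without_embedding_skipped(self, tmp_path, chain_graph):
        tp = self._tp(tmp_path, chain_graph, [("R1", C, "IDA", "F")], ["R1", "Q"])
        emb = EmbeddingMatrix.from_mapping({"R1": [1, 0]})
        assert embedding_transfer(emb, tp, {"Q"}, graph=chain_graph).records == []


class TestTransferMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_ancestor_scores_dominate_without_repropagation(self, seed, tmp_path):
        from funcbench.fixtures import (FixtureConfig, make_ontology,
                                        make_release_pair,
                                        make_similarity_and_embeddings)
        from funcbench import parse_fasta

        d = tmp_path / f"w{seed}"
        fc = FixtureConfig(seed=seed, n_proteins=15, n_terms=20)
        g = make_ontology(fc)
        paths = make_release_pair(fc, g, d)
        tp = build_timepoint(paths["gaf_t0"], paths["fasta_t0"], g, fc.t0_id)
        seqs = parse_fasta(paths["fasta_t0"], fc.t0_id).sequences
        sims = make_similarity_and_embeddings(seqs, tp.training_set, fc, d)
        hits = SimilarityHitTable.read_blast_tabular(sims["hits"])
        emb = EmbeddingMatrix.read_tsv(sims["embeddings"])
        for ps in (
            blast_transfer(hits, tp, tp.test_set, g),
            embedding_transfer(emb, tp, tp.test_set, graph=g),
        ):
            by_protein = ps.by_protein()
            for protein, scores in by_protein.items():
                for term, score in scores.items():
                    for anc in ancestors(g, term):
                        if anc in scores:
                            assert scores[anc] >= score


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKVLAMKVLA", "MKVLAMKVLA") == 1.0

    def test_single_mismatch(self):
        assert pairwise_identity("AAAA", "AATA") == 0.75

    def test_fully_dissimilar(self):
        assert pairwise_identity("AAAA", "WWWW") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")

    @pytest.mark.parametrize("seed", range(5))
    def test_match_count_equals_alignment_oracle(self, seed):
        # the DP maximises matches with free gaps; Biopython's global aligner
        # with the same scoring is an independent oracle for that maximum
        from Bio import Align

        rng = np.random.default_rng(seed)
        alpha = list("ACDEFG")
        a = "".join(rng.choice(alpha, size=12))
        b = "".join(rng.choice(alpha, size=15))
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = 0
        aligner.extend_gap_score = 0
        best = aligner.score(a, b)
        ident = pairwise_identity(a, b)
        # alignment length is between max(len) and len(a)+len(b)
        assert best / (len(a) + len(b)) <= ident <= best / max(len(a), len(b))


class TestPredictionSetIO:
    def test_round_trip(self, tmp_path):
        from funcbench.baselines import PredictionRecord

        ps = PredictionSet("m", [PredictionRecord("P1", C, 0.53),
                                 PredictionRecord("P2", B, 1.0)])
        p = tmp_path / "pred.tsv"
        ps.write_tsv(p)
        back = PredictionSet.read_tsv(p, "m")
        assert {(r.protein, r.term, r.score) for r in back.records} == {
            ("P1", C, 0.53), ("P2", B, 1.0)
        }
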