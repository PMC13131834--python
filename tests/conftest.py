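import json
from pathlib import Path

import pytest

from funcbench import build_ground_truth, build_timepoint, parse_obo
from funcbench.fixtures import FixtureConfig, make_ontology, make_release_pair

# Minimal molecular-function ontology: a chain A <- B <- C plus a sibling
# D of C (both children of B), used across the unit tests.
CHAIN_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: A (root)
namespace: molecular_function

[Term]
id: GO:0000002
name: B
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: molecular_function
is_a: GO:0000002

[Term]
id: GO:0000004
name: D (false sibling of C)
namespace: molecular_function
is_a: GO:0000002
"""

DIAMOND_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: A
namespace: molecular_function

[Term]
id: GO:0000002
name: B
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: molecular_function
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: D
namespace: molecular_function
is_a: GO:0000002
is_a: GO:0000003
"""

A, B, C, D = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"


def write_gaf(path, rows, version="2.2"):
    """rows: (protein, term, evidence, aspect_letter[, qualifier])."""
    with open(path, "w") as fh:
        fh.write(f"!gaf-version: {version}\n")
        for row in rows:
            protein, term, evidence, aspect = row[:4]
            qualifier = row[4] if len(row) > 4 else ""
            fields = [
                "UniProtKB", protein, protein, qualifier, term,
                "GO_REF:0000001", evidence, "", aspect, "", "", "protein",
                "taxon:9606", "20250101", "Test", "", "",
            ]
            fh.write("\t".join(fields) + "\n")
    return path


def write_fasta(path, sequences):
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n{seq}\n")
    return path


@pytest.fixture
def chain_graph(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(CHAIN_OBO)
    return parse_obo(p)


@pytest.fixture
def diamond_graph(tmp_path):
    p = tmp_path / "diamond.obo"
    p.write_text(DIAMOND_OBO)
    return parse_obo(p)


class World:
    """A fully built synthetic study: ontology, releases, time points, window."""

    def __init__(self, root: Path, config: FixtureConfig):
        self.config = config
        self.dir = root
        self.graph = make_ontology(config, root / "ontology.obo")
        self.paths = make_release_pair(config, self.graph, root)
        with open(self.paths["manifest"]) as fh:
            self.manifest = json.load(fh)
        self.tp0 = build_timepoint(
            self.paths["gaf_t0"], self.paths["fasta_t0"], self.graph, config.t0_id
        )
        self.tp1 = build_timepoint(
            self.paths["gaf_t1"], self.paths["fasta_t1"], self.graph, config.t1_id
        )
        self.window = build_ground_truth(self.tp0, self.tp1, self.graph)


def build_world(root: Path, **kwargs) -> World:
    root.mkdir(parents=True, exist_ok=True)
    return World(root, FixtureConfig(**kwargs))


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """Default-scale synthetic study, shared across tests (seed 0)."""
    return build_world(tmp_path_factory.mktemp("world"), seed=0)
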