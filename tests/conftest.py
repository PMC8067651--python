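import dendropy
import pandas as pd
import pytest

from funred import (
    GenomeRecord,
    OtuTable,
    ReferenceDatabase,
    SimulationConfig,
    simulate_world,
)

FOUR_LEAF_NEWICK = "((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture
def four_leaf_tree() -> dendropy.Tree:
    """Balanced 4-leaf tree: sister distance 2, cross-cherry distance 4."""
    return make_tree(FOUR_LEAF_NEWICK)


def make_db(
    tree: dendropy.Tree,
    presence: dict[str, dict[str, float]],
    sequences: dict[str, str] | None = None,
    abundance: dict[str, dict[str, float]] | None = None,
    pathway_map: dict[str, set[str]] | None = None,
) -> ReferenceDatabase:
    """Assemble a ReferenceDatabase directly from explicit matrices."""
    refs = sorted(presence)
    kos = sorted({ko for row in presence.values() for ko in row})
    if sequences is None:
        # distinct, mutually dissimilar placeholder sequences
        bases = ["ACGT", "TGCA", "GGCC", "ATAT", "CCGG", "TATA", "AACC", "GGTT"]
        sequences = {rid: bases[i % len(bases)] * 25 for i, rid in enumerate(refs)}
    pres = pd.DataFrame(0.0, index=refs, columns=kos)
    abund = pd.DataFrame(0.0, index=refs, columns=kos)
    for rid, row in presence.items():
        for ko, v in row.items():
            pres.at[rid, ko] = v
            abund.at[rid, ko] = (abundance or {}).get(rid, {}).get(ko, float(v))
    return ReferenceDatabase(
        threshold=0.99,
        ref_sequences={rid: sequences[rid] for rid in refs},
        association_matrix=abund,
        presence_fraction=pres,
        tree=tree,
        pathway_map=pathway_map or {},
    )


@pytest.fixture
def four_member_db(four_leaf_tree) -> ReferenceDatabase:
    """4 detected references; K1 in one member, K2 in all, K3 in the A/C pair."""
    presence = {
        "A": {"K1": 1.0, "K2": 1.0, "K3": 1.0},
        "B": {"K1": 0.0, "K2": 1.0, "K3": 0.0},
        "C": {"K1": 0.0, "K2": 1.0, "K3": 1.0},
        "D": {"K1": 0.0, "K2": 1.0, "K3": 0.0},
    }
    return make_db(four_leaf_tree, presence)


def one_otu_per_ref(db: ReferenceDatabase, counts: list[float] | None = None, sample: str = "s1") -> OtuTable:
    """An OTU table whose OTUs are exactly the reference sequences."""
    refs = sorted(db.ref_sequences)
    counts = counts or [10.0] * len(refs)
    frame = pd.DataFrame({sample: counts}, index=[f"otu_{r}" for r in refs])
    seqs = {f"otu_{r}": db.ref_sequences[r] for r in refs}
    return OtuTable(counts=frame, sequences=seqs)


@pytest.fixture(scope="session")
def small_world():
    """A 20-genome synthetic world shared by the heavier cross-module tests."""
    return simulate_world(SimulationConfig(seed=7, n_genomes=20, n_communities=3, community_size=10))


@pytest.fixture
def three_genomes() -> list[GenomeRecord]:
    """Mutually dissimilar 16S sequences, simple KO tables, mixed copy numbers."""
    seq1 = "ACGT" * 100
    seq2 = "TTGG" * 100
    seq3 = "CAAC" * 100
    return [
        GenomeRecord("gA", [seq1, seq1], {"K00001": 4, "K00002": 2}),
        GenomeRecord("gB", [seq2], {"K00001": 3}),
        GenomeRecord("gC", [seq3, seq3, seq3], {"K00002": 6, "K00003": 3}),
    ]
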