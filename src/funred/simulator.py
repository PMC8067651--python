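"""Synthetic genomes, communities, and ground truth for end-to-end validation.

The simulator stands in for a public genome repository: it draws a random
Yule (pure-birth) phylogeny over genomes, evolves a 16S rRNA gene down the
tree by per-site substitutions, evolves gene-family (KO) presence by
gain/loss flips along branches, and assigns each genome a 16S copy number
with identical paralogs. Communities are random genome subsets whose 16S
sequences are clustered into OTUs, exactly the situation an amplicon survey
produces — except that here the true tree and the true per-genome function
presence are known, so the accuracy of the 16S-based redundancy prediction
can be measured directly.

``run_validation`` replays the redundancy-index accuracy experiment: many
random communities, each predicted from 16S data via the full pipeline
(reference database build, nearest-neighbour search, redundancy indices) and
compared by Spearman rank correlation against the indices computed straight
from the genomes on the true tree.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .nn_search import run_ref_search
from .prediction import OtuTable
from .redundancy import calculate_fri, fri_from_presence
from .refdb import (
    GenomeRecord,
    ReferenceDatabase,
    build_reference_database,
    cluster_sequences,
    patristic_distance_matrix,
)

logger = logging.getLogger("funred")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic world.

    Branch lengths are in units of the tree height (the tree is rescaled so
    the deepest leaf sits at distance 1 from the root). ``substitution_rate``
    is the expected number of substitutions per site over one unit of branch
    length; the default 0.10 yields within-community 16S identities from
    roughly 82% (deepest splits) up to >99% for sister taxa — a realistic
    amplicon spread. ``gain_loss_rate`` is the per-unit-branch flip rate of
    non-core gene families; ``core_fraction`` of the families are present in
    every genome.
    """

    seed: int = 0
    n_genomes: int = 100
    ssu_length: int = 400
    substitution_rate: float = 0.10
    n_functions: int = 300
    core_fraction: float = 0.2
    gain_loss_rate: float = 0.3
    copy_number_range: tuple[int, int] = (1, 4)
    n_communities: int = 10
    community_size: int = 30
    otu_cluster_identity: float = 0.97
    ref_cluster_identity: float = 0.99
    min_identity: float = 97.0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.community_size > self.n_genomes:
            raise ValueError("community_size cannot exceed n_genomes")
        if self.ssu_length < 1 or self.n_functions < 1:
            raise ValueError("ssu_length and n_functions must be positive")
        for rate in (self.substitution_rate, self.gain_loss_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        lo, hi = self.copy_number_range
        if not 1 <= lo <= hi:
            raise ValueError("copy_number_range must satisfy 1 <= lo <= hi")


@dataclass
class SimulatedWorld:
    """A genome pool with its true phylogeny and true function presence."""

    config: SimulationConfig
    true_tree: dendropy.Tree
    genomes: list[GenomeRecord]
    function_presence: pd.DataFrame  # genome x KO, boolean
    ssu_by_genome: dict[str, str] = field(default_factory=dict)
    _distance_matrix: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def distance_matrix(self) -> pd.DataFrame:
        """Patristic distances between all genomes on the true tree, cached."""
        if self._distance_matrix is None:
            self._distance_matrix = patristic_distance_matrix(self.true_tree)
        return self._distance_matrix


@dataclass
class CommunitySample:
    """One simulated community: its OTU table and its ground truth."""

    otu_table: OtuTable
    truth_presence: pd.DataFrame  # sampled genome x KO, boolean
    genome_ids: list[str]
    sample_id: str


def _mutate(seq_codes: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p_sub, to a uniformly random other base."""
    out = seq_codes.copy()
    sites = np.flatnonzero(rng.random(len(out)) < p_sub)
    if len(sites):
        # shift by 1..3 mod 4: always a different base, uniform over the other three
        out[sites] = (out[sites] + rng.integers(1, 4, size=len(sites))) % 4
    return out


def _yule_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth (Yule) tree over ``n_tips`` leaves, rescaled to unit height.

    Lineages split at rate 1 each; a final exponential waiting time separates
    the last speciation from the present, so every terminal branch has
    strictly positive length (all leaves are contemporaneous).
    """
    namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node.birth_time = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        parent = active.pop(int(rng.integers(k)))
        parent.split_time = t
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            active.append(child)
    present = t + rng.exponential(1.0 / len(active))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        end = getattr(node, "split_time", present)
        node.edge.length = end - node.birth_time
    for edge in tree.preorder_edge_iter():  # unit height
        if edge.length is not None and present > 0:
            edge.length /= present
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = namespace.new_taxon(f"g{i:0{width}d}")
        leaf.taxon = taxon
    return tree


def simulate_world(config: SimulationConfig) -> SimulatedWorld:
    """Generate a genome pool: tree, 16S sequences, function presence, copy numbers.

    Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, seq_seed, fun_seed, count_seed, copy_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]

    tree = _yule_tree(config.n_genomes, np.random.default_rng(tree_seed))

    seq_rng = np.random.default_rng(seq_seed)
    root_codes = seq_rng.integers(0, 4, size=config.ssu_length)
    codes_by_node: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            codes_by_node[id(node)] = root_codes
        else:
            branch = node.edge.length or 0.0
            p_sub = 1.0 - math.exp(-config.substitution_rate * branch)
            codes_by_node[id(node)] = _mutate(codes_by_node[id(node.parent_node)], p_sub, seq_rng)
    ssu_by_genome = {
        leaf.taxon.label: "".join(_BASES[codes_by_node[id(leaf)]])
        for leaf in tree.leaf_node_iter()
    }

    kos = [f"K{i:05d}" for i in range(1, config.n_functions + 1)]
    n_core = round(config.core_fraction * config.n_functions)
    fun_rng = np.random.default_rng(fun_seed)
    n_var = config.n_functions - n_core
    state_by_node: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state_by_node[id(node)] = fun_rng.random(n_var) < 0.5
        else:
            branch = node.edge.length or 0.0
            p_flip = 1.0 - math.exp(-config.gain_loss_rate * branch)
            flips = fun_rng.random(n_var) < p_flip
            state_by_node[id(node)] = state_by_node[id(node.parent_node)] ^ flips
    genome_ids = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    presence = pd.DataFrame(True, index=genome_ids, columns=kos)
    for leaf in tree.leaf_node_iter():
        presence.loc[leaf.taxon.label, kos[n_core:]] = state_by_node[id(leaf)]

    count_rng = np.random.default_rng(count_seed)
    copy_rng = np.random.default_rng(copy_seed)
    lo, hi = config.copy_number_range
    genomes: list[GenomeRecord] = []
    for gid in genome_ids:
        present_kos = presence.columns[presence.loc[gid]]
        ko_counts = {ko: int(count_rng.integers(1, 4)) for ko in present_kos}
        n_copies = int(copy_rng.integers(lo, hi + 1))
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                ssu_sequences=[ssu_by_genome[gid]] * n_copies,
                ko_counts=ko_counts,
            )
        )
    return SimulatedWorld(
        config=config,
        true_tree=tree,
        genomes=genomes,
        function_presence=presence,
        ssu_by_genome=ssu_by_genome,
    )


def reference_tree_from_truth(world: SimulatedWorld, centroid_ids: list[str]) -> dendropy.Tree:
    """Restrict the true tree to the centroid genomes, relabeled to reference ids.

    Pruning preserves patristic distances among the kept leaves, so the
    resulting guide tree carries the true phylogenetic signal for the
    redundancy indices (tree inference itself is not under test here).
    """
    genome_of = {cid: cid.rsplit("|", 1)[0] for cid in centroid_ids}
    if len(set(genome_of.values())) != len(genome_of):
        raise ValueError("two centroids from one genome cannot share a tree leaf")
    pruned = copy.deepcopy(world.true_tree)  # own taxa: relabeling must not touch the original
    pruned.retain_taxa_with_labels(sorted(set(genome_of.values())))
    rename = {gid: cid for cid, gid in genome_of.items()}
    for leaf in pruned.leaf_node_iter():
        leaf.taxon.label = rename[leaf.taxon.label]
    return pruned


def build_world_database(world: SimulatedWorld, use_true_tree: bool = True) -> ReferenceDatabase:
    """Reference database over the whole genome pool at the reference threshold.

    With ``use_true_tree`` (default) the guide tree is the true tree pruned
    to centroid genomes; otherwise it is re-inferred by neighbour joining.
    Pools where two centroids fall in one genome (possible only with
    divergent paralogs, which the defaults do not generate) fall back to the
    rebuilt tree.
    """
    db = build_reference_database(
        world.genomes, threshold=world.config.ref_cluster_identity, tree="rebuild"
    )
    if use_true_tree:
        try:
            true_guide = reference_tree_from_truth(world, list(db.ref_sequences))
        except ValueError:
            logger.warning("centroid collision within a genome; keeping rebuilt NJ tree")
        else:
            db.tree = true_guide
            db._distance_matrix = None
    return db


def sample_community(
    world: SimulatedWorld, community_index: int, config: SimulationConfig | None = None
) -> CommunitySample:
    """Draw a random genome subset and turn its 16S genes into an OTU table.

    The subset's 16S sequences (all copies) are clustered at the OTU
    identity; each OTU is represented by its longest sequence and its count
    is the number of member 16S copies. Deterministic given the world seed
    and the community index.
    """
    config = config or world.config
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[config.seed, 1000003, community_index]))
    ids = world.genome_ids
    chosen = sorted(rng.choice(len(ids), size=config.community_size, replace=False).tolist())
    genome_ids = [ids[i] for i in chosen]

    seq_records = [
        (f"{g.genome_id}|{i}", seq)
        for g in world.genomes
        if g.genome_id in set(genome_ids)
        for i, seq in enumerate(g.ssu_sequences, start=1)
    ]
    clusters = cluster_sequences(seq_records, config.otu_cluster_identity)
    seq_by_id = dict(seq_records)
    sample_id = f"community{community_index}"
    counts = pd.DataFrame(
        {sample_id: [float(len(cl.member_seq_ids)) for cl in clusters]},
        index=[cl.centroid_id for cl in clusters],
    )
    otu_table = OtuTable(
        counts=counts, sequences={cl.centroid_id: seq_by_id[cl.centroid_id] for cl in clusters}
    )
    truth = world.function_presence.loc[genome_ids]
    return CommunitySample(
        otu_table=otu_table, truth_presence=truth, genome_ids=genome_ids, sample_id=sample_id
    )


def oracle_fri(
    world: SimulatedWorld, genome_ids: list[str], variant: str = "rfri"
) -> dict[str, float]:
    """Redundancy indices straight from true presence on the true tree.

    Same formula as the 16S pipeline, with the sampled genomes as the
    detected members and the true function presence — no sequence step. The
    reference point for validating the prediction.
    """
    if not set(genome_ids) <= set(world.genome_ids):
        raise ValueError("sampled set contains unknown genomes")
    presence = {
        gid: set(world.function_presence.columns[world.function_presence.loc[gid]])
        for gid in genome_ids
    }
    dist = world.distance_matrix()
    afri, rfri = fri_from_presence(presence, dist, list(world.function_presence.columns))
    if variant == "rfri":
        return rfri
    if variant == "afri":
        return afri
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class ValidationReport:
    """Per-community oracle-vs-predicted correlations and their medians."""

    per_community: pd.DataFrame  # columns: community, n_functions, spearman_rfri, spearman_afri
    median_rfri: float
    median_afri: float


def run_validation(config: SimulationConfig, world: SimulatedWorld | None = None) -> ValidationReport:
    """Replay the redundancy-index accuracy experiment on synthetic data.

    For each community: predict rFRI/aFRI from the OTU table through the full
    pipeline, compute the oracle indices from true genome presence on the
    true tree, and correlate the two (Spearman) over the functions present in
    at least two sampled genomes. Communities with fewer than two informative
    functions, or with no rank variation, are excluded and logged.
    """
    world = world or simulate_world(config)
    db = build_world_database(world)
    rows = []
    for k in range(config.n_communities):
        community = sample_community(world, k, config)
        hits = run_ref_search(
            community.otu_table.query_records(), db, min_identity=config.min_identity
        )
        fri = calculate_fri(
            community.otu_table, hits, db, min_identity=config.min_identity
        )
        if community.sample_id not in fri.rfri.index:
            logger.warning("community %d: no detected members; excluded", k)
            continue
        informative = [
            ko
            for ko in world.function_presence.columns
            if int(community.truth_presence[ko].sum()) >= 2
        ]
        if len(informative) < 2:
            logger.warning("community %d: fewer than 2 informative functions; excluded", k)
            continue
        oracle_r = oracle_fri(world, community.genome_ids, "rfri")
        oracle_a = oracle_fri(world, community.genome_ids, "afri")
        pred_r = fri.rfri.loc[community.sample_id]
        pred_a = fri.afri.loc[community.sample_id]
        vec_oracle_r = np.array([oracle_r[ko] for ko in informative])
        vec_oracle_a = np.array([oracle_a[ko] for ko in informative])
        vec_pred_r = np.array([pred_r.get(ko, 0.0) for ko in informative])
        vec_pred_a = np.array([pred_a.get(ko, 0.0) for ko in informative])
        rho_r = stats.spearmanr(vec_oracle_r, vec_pred_r).statistic
        rho_a = stats.spearmanr(vec_oracle_a, vec_pred_a).statistic
        if np.isnan(rho_r) or np.isnan(rho_a):
            logger.warning("community %d: degenerate ranks; excluded", k)
            continue
        rows.append(
            {
                "community": k,
                "n_functions": len(informative),
                "spearman_rfri": float(rho_r),
                "spearman_afri": float(rho_a),
            }
        )
    per_community = pd.DataFrame(rows, columns=["community", "n_functions", "spearman_rfri", "spearman_afri"])
    if per_community.empty:
        raise ValueError("no community produced a usable correlation")
    return ValidationReport(
        per_community=per_community,
        median_rfri=float(per_community["spearman_rfri"].median()),
        median_afri=float(per_community["spearman_afri"].median()),
    )
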