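"""Reference databases linking 16S rRNA sequences to KEGG-ortholog profiles.

A reference database is built from genome records, each carrying the 16S
rRNA gene sequences found in the genome and a table of KO (KEGG Orthology)
gene counts. Building proceeds in three steps:

1. all 16S sequences are pooled, sorted by decreasing length, and greedily
   clustered at an identity threshold (0.99 and 1.00 are the conventional
   choices); the longest sequence of each cluster becomes the reference
   sequence;
2. each genome's KO counts are divided by its 16S copy number, so multi-copy
   taxa are not over-weighted in downstream predictions;
3. the normalized profiles of a cluster's member genomes are averaged into
   one functional reference profile per reference sequence, after scaling
   each genome's profile by the number of its 16S copies that landed in the
   cluster. Alongside the abundance profile, the fraction of member genomes
   possessing each KO is recorded (used for presence/absence binarization by
   the redundancy index).

The database also holds a phylogeny over the reference sequences (supplied,
or rebuilt by neighbour joining on alignment-identity distances) and a
KO -> pathway map used for pathway-level summaries.
"""

from __future__ import annotations

import copy
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import io as fio
from .align import pairwise_identity

logger = logging.getLogger("funred")

USER_PREFIX = "user:"

AveragingMode = Literal["scaled_mean", "weighted_mean"]


@dataclass
class GenomeRecord:
    """One genome: its 16S rRNA gene sequences and its KO gene counts."""

    genome_id: str
    ssu_sequences: list[str]
    ko_counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(count < 0 for count in self.ko_counts.values()):
            raise ValueError(f"genome {self.genome_id}: negative KO count")

    @property
    def n_ssu(self) -> int:
        return len(self.ssu_sequences)


@dataclass
class SequenceCluster:
    """A greedy centroid cluster of 16S sequences.

    ``member_seq_ids`` are individual 16S gene ids of the form
    ``<genome_id>|<n>``; ``members`` aggregates them per genome as
    ``(genome_id, copies_in_cluster)`` pairs.
    """

    cluster_id: str
    centroid_id: str
    member_seq_ids: list[str]

    @property
    def members(self) -> list[tuple[str, int]]:
        per_genome: dict[str, int] = {}
        for sid in self.member_seq_ids:
            gid = sid.rsplit("|", 1)[0]
            per_genome[gid] = per_genome.get(gid, 0) + 1
        return list(per_genome.items())


def normalize_profile(ko_counts: Mapping[str, int], n_ssu: int) -> dict[str, float]:
    """Divide each KO count by the genome's 16S copy number.

    A genome without a detected 16S gene cannot be placed in the database, so
    ``n_ssu`` of zero is an error.
    """
    if n_ssu < 1:
        raise ValueError("genome without a detected 16S rRNA gene (n_ssu = 0)")
    return {ko: count / n_ssu for ko, count in ko_counts.items()}


def cluster_sequences(
    sequences: Sequence[tuple[str, str]], threshold: float
) -> list[SequenceCluster]:
    """Greedy length-sorted centroid clustering at a global-identity threshold.

    Sequences are processed longest-first (length ties broken lexicographically
    by id); each sequence joins the first existing centroid it matches at or
    above ``threshold`` global identity, otherwise it founds a new cluster.
    Deterministic given the input set.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    for sid, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
    ordered = sorted(sequences, key=lambda rec: (-len(rec[1]), rec[0]))
    min_identity = threshold * 100.0 - 1e-9
    centroid_seqs: list[str] = []
    clusters: list[SequenceCluster] = []
    decided: dict[str, int] = {}  # exact-duplicate memo: sequence -> cluster index
    for sid, seq in ordered:
        idx = decided.get(seq)
        if idx is None:
            for i, cseq in enumerate(centroid_seqs):
                if pairwise_identity(seq, cseq) >= min_identity:
                    idx = i
                    break
        if idx is None:
            idx = len(clusters)
            clusters.append(
                SequenceCluster(cluster_id=f"cluster{idx + 1}", centroid_id=sid, member_seq_ids=[])
            )
            centroid_seqs.append(seq)
        decided[seq] = idx
        clusters[idx].member_seq_ids.append(sid)
    return clusters


def build_cluster_profile(
    members: Sequence[tuple[Mapping[str, float], int]],
    mode: AveragingMode = "scaled_mean",
) -> tuple[dict[str, float], dict[str, float]]:
    """Average member-genome profiles into one cluster reference profile.

    Each member is ``(normalized profile, copies_in_cluster)``. The default
    ``scaled_mean`` multiplies each genome's normalized profile by its copy
    multiplicity in the cluster and divides by the number of member genomes;
    ``weighted_mean`` divides by the total copies instead. Returns
    ``(abundance profile, presence fraction per KO)``; KOs absent from every
    member are dropped from the abundance profile, and presence is the share
    of member genomes with a nonzero count.
    """
    if not members:
        raise ValueError("cluster with zero member genomes")
    n_genomes = len(members)
    denominator = n_genomes if mode == "scaled_mean" else sum(c for _, c in members)
    abundance: dict[str, float] = {}
    presence: dict[str, float] = {}
    kos: list[str] = []
    seen: set[str] = set()
    for profile, _ in members:
        for ko in profile:
            if ko not in seen:
                seen.add(ko)
                kos.append(ko)
    for ko in kos:
        total = sum(copies * profile.get(ko, 0.0) for profile, copies in members)
        n_with = sum(1 for profile, _ in members if profile.get(ko, 0.0) > 0)
        presence[ko] = n_with / n_genomes
        if total > 0:
            abundance[ko] = total / denominator
    return abundance, presence


@dataclass
class ReferenceDatabase:
    """16S reference sequences bound to KO profiles, a phylogeny, and pathways.

    ``association_matrix`` and ``presence_fraction`` are reference x KO
    DataFrames sharing the same index; every reference id is a leaf of
    ``tree``.
    """

    threshold: float
    ref_sequences: dict[str, str]
    association_matrix: pd.DataFrame
    presence_fraction: pd.DataFrame
    tree: dendropy.Tree
    pathway_map: dict[str, set[str]] = field(default_factory=dict)
    provenance: Literal["default", "user"] = "default"
    _distance_matrix: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.association_matrix.index.equals(self.presence_fraction.index):
            raise ValueError("association matrix and presence fractions have different reference ids")
        if set(self.association_matrix.index) != set(self.ref_sequences):
            raise ValueError("association matrix index does not match reference sequences")
        leaves = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = set(self.ref_sequences) - leaves
        if missing:
            raise ValueError(f"reference ids missing from tree: {sorted(missing)[:5]}")
        values = self.presence_fraction.values
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValueError("presence fractions outside [0, 1]")

    @property
    def reference_ids(self) -> list[str]:
        return list(self.association_matrix.index)

    def distance_matrix(self) -> pd.DataFrame:
        """Patristic (branch-length path) distances between all tree leaves, cached."""
        if self._distance_matrix is None:
            self._distance_matrix = patristic_distance_matrix(self.tree)
        return self._distance_matrix

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fio.write_fasta(directory / "ref_sequences.fasta", sorted(self.ref_sequences.items()))
        fio.write_matrix_tsv(directory / "association_matrix.tsv", self.association_matrix, "reference_id")
        fio.write_matrix_tsv(directory / "presence_fraction.tsv", self.presence_fraction, "reference_id")
        fio.write_tree(directory / "tree.nwk", self.tree)
        fio.write_pathway_map(directory / "pathway_map.tsv", self.pathway_map)
        fio.write_json(
            directory / "meta.json",
            {"threshold": self.threshold, "provenance": self.provenance, "format": "funred-refdb-1"},
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceDatabase":
        directory = Path(directory)
        meta = fio.read_json(directory / "meta.json")
        return cls(
            threshold=float(meta["threshold"]),
            ref_sequences=dict(fio.read_fasta(directory / "ref_sequences.fasta")),
            association_matrix=fio.read_matrix_tsv(directory / "association_matrix.tsv"),
            presence_fraction=fio.read_matrix_tsv(directory / "presence_fraction.tsv"),
            tree=fio.read_tree(directory / "tree.nwk"),
            pathway_map=fio.read_pathway_map(directory / "pathway_map.tsv"),
            provenance=meta.get("provenance", "default"),
        )


def patristic_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf x leaf matrix of branch-length path distances."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def nj_tree_from_sequences(sequences: Mapping[str, str]) -> dendropy.Tree:
    """Neighbour-joining guide tree from (1 - identity) distances, midpoint-rooted.

    A desk-scale stand-in for a curated reference phylogeny: any additive tree
    over the references satisfies the redundancy-index contract.
    """
    ids = sorted(sequences)
    if len(ids) == 1:
        tree = dendropy.Tree.get(data=f"({ids[0]}:0.0);", schema="newick", preserve_underscores=True)
        return tree
    dist = {
        (a, b): 1.0 - pairwise_identity(sequences[a], sequences[b]) / 100.0
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    }
    if len(ids) == 2:
        a, b = ids
        half = dist[(a, b)] / 2.0
        return dendropy.Tree.get(data=f"({a}:{half},{b}:{half});", schema="newick", preserve_underscores=True)
    buf = _io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for a in ids:
        row = [a]
        for b in ids:
            if a == b:
                row.append("0")
            else:
                key = (a, b) if (a, b) in dist else (b, a)
                row.append(repr(dist[key]))
        buf.write(",".join(row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.reroot_at_midpoint()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0  # NJ can emit tiny negative branches
    return tree


def build_reference_database(
    genomes: Iterable[GenomeRecord],
    threshold: float = 0.99,
    tree: dendropy.Tree | Literal["rebuild"] = "rebuild",
    pathway_map: Mapping[str, set[str]] | None = None,
    cluster: bool = True,
    provenance: Literal["default", "user"] = "default",
    averaging: AveragingMode = "scaled_mean",
) -> ReferenceDatabase:
    """Build a reference database from genome records.

    With ``cluster=False`` every 16S sequence founds its own reference (the
    small-genome-set path that bypasses clustering). ``tree`` may be a
    ready-made phylogeny whose leaves are the reference ids, or ``"rebuild"``
    to infer a neighbour-joining guide tree from the reference sequences.
    Genomes without any 16S sequence are excluded with a warning; duplicate
    genome ids are an error.
    """
    usable: list[GenomeRecord] = []
    seen_ids: set[str] = set()
    for genome in genomes:
        if genome.genome_id in seen_ids:
            raise ValueError(f"duplicate genome id {genome.genome_id!r}")
        seen_ids.add(genome.genome_id)
        if genome.n_ssu == 0:
            logger.warning("genome %s has no 16S sequence; excluded from database", genome.genome_id)
            continue
        usable.append(genome)
    if not usable:
        raise ValueError("no genome with a 16S sequence; cannot build a database")
    by_id = {g.genome_id: g for g in usable}

    seq_records = [
        (f"{g.genome_id}|{i}", seq)
        for g in usable
        for i, seq in enumerate(g.ssu_sequences, start=1)
    ]
    if cluster:
        clusters = cluster_sequences(seq_records, threshold)
    else:
        clusters = [
            SequenceCluster(cluster_id=f"cluster{i + 1}", centroid_id=sid, member_seq_ids=[sid])
            for i, (sid, _) in enumerate(seq_records)
        ]
    seq_by_id = dict(seq_records)

    ref_sequences: dict[str, str] = {}
    abundance_rows: dict[str, dict[str, float]] = {}
    presence_rows: dict[str, dict[str, float]] = {}
    for cl in clusters:
        member_profiles = [
            (normalize_profile(by_id[gid].ko_counts, by_id[gid].n_ssu), copies)
            for gid, copies in cl.members
        ]
        abundance, presence = build_cluster_profile(member_profiles, mode=averaging)
        ref_sequences[cl.centroid_id] = seq_by_id[cl.centroid_id]
        abundance_rows[cl.centroid_id] = abundance
        presence_rows[cl.centroid_id] = presence

    ref_ids = list(ref_sequences)
    all_kos = sorted({ko for row in presence_rows.values() for ko in row})
    association = pd.DataFrame(0.0, index=ref_ids, columns=all_kos)
    presence_fraction = pd.DataFrame(0.0, index=ref_ids, columns=all_kos)
    for rid in ref_ids:
        for ko, value in abundance_rows[rid].items():
            association.at[rid, ko] = value
        for ko, value in presence_rows[rid].items():
            presence_fraction.at[rid, ko] = value

    if isinstance(tree, str):
        if tree != "rebuild":
            raise ValueError(f"unknown tree mode {tree!r}")
        guide_tree = nj_tree_from_sequences(ref_sequences)
    else:
        guide_tree = tree

    return ReferenceDatabase(
        threshold=threshold,
        ref_sequences=ref_sequences,
        association_matrix=association,
        presence_fraction=presence_fraction,
        tree=guide_tree,
        pathway_map={ko: set(pws) for ko, pws in (pathway_map or {}).items()},
        provenance=provenance,
    )


@dataclass
class MergedDatabase:
    """Two-tier handle over a default and a user database.

    User reference ids are exposed with a ``user:`` prefix so the two
    namespaces cannot collide; searches prefer user-tier hits (habitat-
    specific references are assumed closer to the community under study).
    """

    default: ReferenceDatabase
    user: ReferenceDatabase

    def __post_init__(self) -> None:
        prefixed = {self.qualify(rid, "user") for rid in self.user.ref_sequences}
        collisions = prefixed & set(self.default.ref_sequences)
        if collisions:
            raise ValueError(f"reference id collision after prefixing: {sorted(collisions)[:5]}")

    @staticmethod
    def qualify(ref_id: str, source: str) -> str:
        if source == "user" and not ref_id.startswith(USER_PREFIX):
            return USER_PREFIX + ref_id
        return ref_id

    def resolve(self, ref_id: str) -> tuple[ReferenceDatabase, str]:
        if ref_id.startswith(USER_PREFIX):
            return self.user, ref_id[len(USER_PREFIX) :]
        return self.default, ref_id

    @property
    def reference_ids(self) -> list[str]:
        return list(self.default.ref_sequences) + [
            self.qualify(rid, "user") for rid in self.user.ref_sequences
        ]

    def association_row(self, ref_id: str) -> pd.Series:
        db, rid = self.resolve(ref_id)
        return db.association_matrix.loc[rid]

    def presence_row(self, ref_id: str) -> pd.Series:
        db, rid = self.resolve(ref_id)
        return db.presence_fraction.loc[rid]

    @property
    def pathway_map(self) -> dict[str, set[str]]:
        merged = {ko: set(pws) for ko, pws in self.default.pathway_map.items()}
        for ko, pws in self.user.pathway_map.items():
            merged.setdefault(ko, set()).update(pws)
        return merged

    def to_reference_database(self) -> ReferenceDatabase:
        """Flatten both tiers into one database with a rebuilt guide tree.

        Needed when the two tiers must share one phylogeny (redundancy
        indices); the tree is re-inferred by neighbour joining over the union
        of reference sequences.
        """
        sequences = dict(self.default.ref_sequences)
        sequences.update(
            {self.qualify(rid, "user"): seq for rid, seq in self.user.ref_sequences.items()}
        )
        user_assoc = self.user.association_matrix.rename(index=lambda r: self.qualify(r, "user"))
        user_pres = self.user.presence_fraction.rename(index=lambda r: self.qualify(r, "user"))
        association = (
            pd.concat([self.default.association_matrix, user_assoc]).fillna(0.0).sort_index(axis=1)
        )
        presence = pd.concat([self.default.presence_fraction, user_pres]).fillna(0.0).sort_index(axis=1)
        return ReferenceDatabase(
            threshold=self.default.threshold,
            ref_sequences=sequences,
            association_matrix=association,
            presence_fraction=presence,
            tree=nj_tree_from_sequences(sequences),
            pathway_map=self.pathway_map,
            provenance="default",
        )


def merge_databases(default_db: ReferenceDatabase, user_db: ReferenceDatabase) -> MergedDatabase:
    """Combine a default and a user database into a two-tier search handle."""
    user_db = copy.copy(user_db)
    user_db.provenance = "user"
    return MergedDatabase(default=default_db, user=user_db)
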