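"""Functional redundancy indices (aFRI / rFRI) per function and sample.

The functional redundancy index asks, for each function, how widely it is
spread over the phylogeny of a community: a function carried by many,
distantly related members is robust to the loss of any one of them, while a
function confined to one member (or a tight clade) is easily lost. For a
sample with detected members ``M`` and a function ``f`` possessed by the
subset ``M_f``:

    raw(f)  = mean pairwise patristic distance over M_f  x  |M_f| / |M|
    rFRI(f) = raw(f) / mean pairwise patristic distance over M
    aFRI(f) = raw(f) / mean pairwise patristic distance over all tree leaves

rFRI compares functions within one survey; aFRI is normalized by the whole
reference tree, so it is comparable across ecosystems. A function in at most
one member scores exactly 0; a function in all members scores rFRI 1.

Presence of a function in a detected reference is decided from the reference
cluster's per-KO presence fraction, scaled by the number of distinct OTUs
that mapped to the reference: with the default threshold 0.5, a reference
hit by 5 distinct OTUs admits every function present in at least 10% of its
member genomes (more distinct phylotypes behind one reference make it more
likely that some member carries the function). Setting the threshold to 1.0
recovers the strict rule where a function must be present in every member
genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .nn_search import HitTable
from .prediction import CoverageLog, OtuTable, compute_coverage
from .refdb import MergedDatabase, ReferenceDatabase

logger = logging.getLogger("funred")


@dataclass
class FriResult:
    """Absolute and relative functional redundancy indices, sample x KO."""

    afri: pd.DataFrame
    rfri: pd.DataFrame
    coverage: dict[str, CoverageLog] = field(default_factory=dict)


def binarize_presence(
    presence_fraction: Mapping[str, float], k_otus: int, threshold: float = 0.5
) -> set[str]:
    """KOs considered present in a reference hit by ``k_otus`` distinct OTUs.

    A KO is admitted when ``presence_fraction x k_otus`` reaches ``threshold``
    (boundary inclusive): one OTU requires a majority of member genomes,
    5 OTUs admit anything at or above 10%.
    """
    if k_otus < 1:
        raise ValueError("k_otus must be >= 1")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    present: set[str] = set()
    for ko, fraction in presence_fraction.items():
        scaled = fraction * k_otus
        if scaled > threshold or math.isclose(scaled, threshold, rel_tol=1e-9, abs_tol=1e-12):
            present.add(ko)
    return present


def mean_pairwise_distance(tree: dendropy.Tree, leaves: Iterable[str]) -> float:
    """Mean patristic distance over all unordered pairs of the given leaves.

    Zero for at most one leaf (a function found in a single member has no
    phylogenetic spread). Unknown leaf labels are an error.
    """
    labels = sorted(set(leaves))
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    missing = [lb for lb in labels if lb not in taxa]
    if missing:
        raise KeyError(f"leaves not in tree: {missing[:5]}")
    if len(labels) <= 1:
        return 0.0
    pdm = tree.phylogenetic_distance_matrix()
    total = 0.0
    n_pairs = 0
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            total += pdm.patristic_distance(taxa[a], taxa[b])
            n_pairs += 1
    return total / n_pairs


def _subset_mpd(dist: pd.DataFrame, labels: list[str]) -> float:
    if len(labels) <= 1:
        return 0.0
    sub = dist.loc[labels, labels].to_numpy()
    n = len(labels)
    return float(sub[np.triu_indices(n, k=1)].mean())


def fri_from_presence(
    presence: Mapping[str, set[str]],
    distance_matrix: pd.DataFrame,
    kos: Iterable[str],
    tree_mean_distance: float | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Evaluate aFRI/rFRI from an explicit member -> possessed-KO map.

    ``presence`` maps each detected member (a leaf label of the tree behind
    ``distance_matrix``) to the set of KOs it possesses. Returns
    ``(afri, rfri)`` dicts over ``kos``. Shared by the 16S pipeline and by
    direct genome-level evaluation.
    """
    members = sorted(presence)
    if not members:
        raise ValueError("no detected members")
    community_mpd = _subset_mpd(distance_matrix, members)
    if tree_mean_distance is None:
        tree_mean_distance = _subset_mpd(distance_matrix, list(distance_matrix.index))
    afri: dict[str, float] = {}
    rfri: dict[str, float] = {}
    for ko in kos:
        possessing = [m for m in members if ko in presence[m]]
        if len(possessing) <= 1:
            afri[ko] = 0.0
            rfri[ko] = 0.0
            continue
        raw = _subset_mpd(distance_matrix, possessing) * (len(possessing) / len(members))
        rfri[ko] = raw / community_mpd if community_mpd > 0 else 0.0
        afri[ko] = raw / tree_mean_distance if tree_mean_distance > 0 else 0.0
    return afri, rfri


def calculate_fri(
    otu_table: OtuTable,
    hits: HitTable,
    db: ReferenceDatabase | MergedDatabase,
    min_identity: float = 97.0,
    presence_threshold: float = 0.5,
) -> FriResult:
    """Functional redundancy indices for every sample of an OTU table.

    Per sample, the detected members are the references hit by at least one
    passing OTU with nonzero count; each member's possessed-function set
    comes from :func:`binarize_presence` with the member's distinct-OTU
    count. Samples with no detected member are skipped (their coverage log
    still reports the failure). When both indices' denominators degenerate
    (all detected members on one leaf), the indices are reported as 0.

    A merged two-tier database is flattened first so both tiers share one
    guide tree; pre-flatten with ``MergedDatabase.to_reference_database()``
    to amortize that cost over repeated calls.
    """
    if isinstance(db, MergedDatabase):
        db = db.to_reference_database()
    if len(db.ref_sequences) < 2:
        raise ValueError("redundancy indices need a tree with at least 2 leaves")
    missing = [oid for oid in otu_table.otu_ids if oid not in hits.hits]
    if missing:
        raise ValueError(f"OTUs missing from hit table: {missing[:5]}")

    dist = db.distance_matrix()
    tree_mean = _subset_mpd(dist, list(dist.index))
    assignment = {oid: h.ref_id for oid, h in hits.passing(min_identity).items()}
    coverage, _ = compute_coverage(otu_table, hits, min_identity)
    kos = list(db.presence_fraction.columns)

    afri_rows: dict[str, dict[str, float]] = {}
    rfri_rows: dict[str, dict[str, float]] = {}
    for sample in otu_table.sample_ids:
        col = otu_table.counts[sample]
        otus_here = [oid for oid in col.index[col > 0] if oid in assignment]
        if not otus_here:
            logger.warning("sample %s: no passing OTU; redundancy indices skipped", sample)
            continue
        k_otus: dict[str, int] = {}
        for oid in otus_here:
            rid = assignment[oid]
            k_otus[rid] = k_otus.get(rid, 0) + 1
        presence = {
            rid: binarize_presence(
                db.presence_fraction.loc[rid].to_dict(), k, presence_threshold
            )
            for rid, k in k_otus.items()
        }
        afri, rfri = fri_from_presence(presence, dist, kos, tree_mean)
        afri_rows[sample] = afri
        rfri_rows[sample] = rfri

    afri_df = pd.DataFrame.from_dict(afri_rows, orient="index", columns=kos, dtype=float)
    rfri_df = pd.DataFrame.from_dict(rfri_rows, orient="index", columns=kos, dtype=float)
    return FriResult(afri=afri_df, rfri=rfri_df, coverage=coverage)
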