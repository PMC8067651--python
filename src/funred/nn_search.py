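"""Nearest-reference search for OTU representative sequences.

Each query OTU is aligned against every reference sequence and assigned the
reference with the highest percent identity (ties broken by longer reference,
then lexicographic reference id). When a user-supplied habitat-specific
database is present, both tiers are searched and a user-tier hit passing the
identity floor wins regardless of the default tier's identity — habitat-
specific references are assumed to represent the community better than the
closest public genome. Queries matching nothing above the floor stay
unassigned; that is a valid outcome, recorded in the coverage diagnostics
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .align import pairwise_identity
from .io import atomic_open
from .refdb import MergedDatabase, ReferenceDatabase

logger = logging.getLogger("funred")

SHORT_QUERY_WARNING_NT = 100


@dataclass
class NeighborHit:
    otu_id: str
    ref_id: str | None
    identity: float | None
    source: Literal["default", "user", "unassigned"]

    def __post_init__(self) -> None:
        unassigned = self.source == "unassigned"
        if (self.ref_id is None) != unassigned or (self.identity is None) != unassigned:
            raise ValueError("ref_id/identity must be None exactly when source is 'unassigned'")


@dataclass
class HitTable:
    """Per-OTU nearest-neighbour results plus the identity floor used."""

    hits: dict[str, NeighborHit] = field(default_factory=dict)
    min_identity: float = 97.0

    def passing(self, min_identity: float | None = None) -> dict[str, NeighborHit]:
        """Hits at or above the identity floor."""
        floor = self.min_identity if min_identity is None else min_identity
        return {
            oid: h
            for oid, h in self.hits.items()
            if h.identity is not None and h.identity >= floor - 1e-9
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "otu_id": h.otu_id,
                "ref_id": h.ref_id if h.ref_id is not None else "NA",
                "identity": h.identity if h.identity is not None else "NA",
                "source": h.source,
            }
            for h in self.hits.values()
        ]
        return pd.DataFrame(rows, columns=["otu_id", "ref_id", "identity", "source"])

    def save(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame["identity"] = frame["identity"].map(
            lambda v: v if isinstance(v, str) else f"{v:.6g}"
        )
        with atomic_open(path) as fh:
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, min_identity: float = 97.0) -> "HitTable":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        table = cls(min_identity=min_identity)
        for _, row in frame.iterrows():
            unassigned = row["ref_id"] == "NA" or row["source"] == "unassigned"
            table.hits[row["otu_id"]] = NeighborHit(
                otu_id=row["otu_id"],
                ref_id=None if unassigned else row["ref_id"],
                identity=None if unassigned else float(row["identity"]),
                source="unassigned" if unassigned else row["source"],
            )
        return table


def _best_hit(seq: str, db: ReferenceDatabase) -> tuple[str, float] | None:
    """Reference with maximal identity; ties to longer reference, then lexicographic id."""
    best: tuple[str, float] | None = None
    for rid, rseq in db.ref_sequences.items():
        ident = pairwise_identity(seq, rseq)
        if best is None:
            best = (rid, ident)
            continue
        brid, bident = best
        if ident > bident + 1e-12:
            best = (rid, ident)
        elif abs(ident - bident) <= 1e-12:
            lb, lr = len(db.ref_sequences[brid]), len(rseq)
            if lr > lb or (lr == lb and rid < brid):
                best = (rid, ident)
    return best


def run_ref_search(
    queries: Sequence[tuple[str, str]],
    default_db: ReferenceDatabase | MergedDatabase,
    user_db: ReferenceDatabase | None = None,
    min_identity: float = 97.0,
) -> HitTable:
    """Assign each query OTU its nearest reference.

    ``default_db`` may itself be a merged two-tier handle; alternatively a
    separate ``user_db`` is given alongside a plain default database. A
    user-tier hit passing ``min_identity`` is preferred over any default-tier
    hit; otherwise the default-tier hit is taken if it passes; else the OTU
    is left unassigned (best below-floor hit still recorded for diagnostics).
    """
    if not queries:
        raise ValueError("no query sequences")
    if isinstance(default_db, MergedDatabase):
        if user_db is not None:
            raise ValueError("pass either a MergedDatabase or a separate user_db, not both")
        merged = default_db
        default_tier, user_tier = merged.default, merged.user
    else:
        default_tier, user_tier = default_db, user_db

    table = HitTable(min_identity=min_identity)
    cache: dict[str, NeighborHit] = {}
    for oid, seq in queries:
        if oid in table.hits:
            raise ValueError(f"duplicate query OTU id {oid!r}")
        if len(seq) < SHORT_QUERY_WARNING_NT:
            logger.warning("query %s is only %d nt; identities may be unreliable", oid, len(seq))
        cached = cache.get(seq)
        if cached is not None:
            table.hits[oid] = NeighborHit(oid, cached.ref_id, cached.identity, cached.source)
            continue
        default_best = _best_hit(seq, default_tier)
        user_best = _best_hit(seq, user_tier) if user_tier is not None else None
        floor = min_identity - 1e-9
        if user_best is not None and user_best[1] >= floor:
            rid = MergedDatabase.qualify(user_best[0], "user")
            hit = NeighborHit(oid, rid, user_best[1], "user")
        elif default_best is not None and default_best[1] >= floor:
            hit = NeighborHit(oid, default_best[0], default_best[1], "default")
        else:
            hit = NeighborHit(oid, None, None, "unassigned")
        table.hits[oid] = hit
        cache[seq] = hit
    return table


def parse_blast_tabular(
    path: str | Path,
    min_identity: float = 97.0,
    max_evalue: float = 1e-5,
) -> HitTable:
    """Build a HitTable from BLAST tabular output (outfmt 6), as an adapter.

    Expects the standard 12 columns; keeps, per query, the hit with the
    highest percent identity among those with e-value <= ``max_evalue``.
    Provided for users who prefer an external aligner; the built-in search
    never requires it.
    """
    best: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            qid, sid, pident, evalue = parts[0], parts[1], float(parts[2]), float(parts[10])
            if evalue > max_evalue:
                continue
            if qid not in best or pident > best[qid][1]:
                best[qid] = (sid, pident)
    table = HitTable(min_identity=min_identity)
    for qid, (sid, pident) in best.items():
        if pident >= min_identity - 1e-9:
            table.hits[qid] = NeighborHit(qid, sid, pident, "default")
        else:
            table.hits[qid] = NeighborHit(qid, None, None, "unassigned")
    return table
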