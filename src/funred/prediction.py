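"""Functional profile prediction from OTU abundances and nearest-reference hits.

The OTU table is summarized per reference sequence (summing the counts of all
OTUs assigned to the same reference and passing the identity floor), then
multiplied through the association matrix: each sample's raw KO vector is the
abundance-weighted sum of the functional reference profiles of its detected
references. Profiles are reported as relative abundances (each sample's KO
vector sums to 1) and rolled up to KEGG pathways; a KO belonging to several
pathways contributes to each, so the pathway table is not itself normalized.

Coverage of the prediction is logged per sample as FTU (fraction of
taxonomic units unused: OTUs present in the sample but without a passing
reference hit) and FSU (fraction of sequence reads in those unused OTUs) —
high values mean the prediction describes only a small part of the community.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .io import atomic_open
from .nn_search import HitTable
from .refdb import MergedDatabase, ReferenceDatabase

logger = logging.getLogger("funred")


@dataclass
class OtuTable:
    """An OTU x sample count matrix bound to OTU representative sequences."""

    counts: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate OTU ids in table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in table")
        if (self.counts.values < 0).any():
            raise ValueError("negative OTU counts")
        with_counts = self.counts.index[self.counts.sum(axis=1) > 0]
        missing = [oid for oid in with_counts if oid not in self.sequences]
        if missing:
            raise ValueError(f"OTUs with counts but no representative sequence: {missing[:5]}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def query_records(self) -> list[tuple[str, str]]:
        return [(oid, self.sequences[oid]) for oid in self.otu_ids if oid in self.sequences]


@dataclass
class CoverageLog:
    """Prediction coverage for one sample (or the whole dataset)."""

    ftu: float
    fsu: float
    n_otus_used: int
    n_otus_total: int

    def format_line(self, label: str) -> str:
        ftu = "NA" if math.isnan(self.ftu) else f"{self.ftu:.6g}"
        fsu = "NA" if math.isnan(self.fsu) else f"{self.fsu:.6g}"
        return (
            f"{label}\tFTU={ftu}\tFSU={fsu}\t"
            f"otus_used={self.n_otus_used}/{self.n_otus_total}"
        )


@dataclass
class FunctionalProfile:
    """Per-sample KO and pathway relative abundances with coverage diagnostics."""

    ko_relative: pd.DataFrame  # sample x KO, rows sum to 1
    ko_raw: pd.DataFrame  # sample x KO, unnormalized
    pathway_relative: pd.DataFrame  # sample x pathway
    coverage: dict[str, CoverageLog] = field(default_factory=dict)
    dataset_coverage: CoverageLog | None = None


def _passing_otus(hits: HitTable, min_identity: float) -> dict[str, str]:
    """Map of OTU id -> reference id for hits at or above the floor."""
    return {oid: h.ref_id for oid, h in hits.passing(min_identity).items()}


def summarize_by_reference(
    otu_table: OtuTable, hits: HitTable, min_identity: float = 97.0
) -> pd.DataFrame:
    """Sum OTU counts per assigned reference: a reference x sample matrix.

    Only OTUs whose nearest-neighbour identity passes ``min_identity``
    contribute; references hit by no passing OTU get no row.
    """
    missing = [oid for oid in otu_table.otu_ids if oid not in hits.hits]
    if missing:
        raise ValueError(f"OTUs missing from hit table: {missing[:5]}")
    assignment = _passing_otus(hits, min_identity)
    rows: dict[str, pd.Series] = {}
    for oid in otu_table.otu_ids:
        rid = assignment.get(oid)
        if rid is None:
            continue
        if rid in rows:
            rows[rid] = rows[rid] + otu_table.counts.loc[oid]
        else:
            rows[rid] = otu_table.counts.loc[oid].copy()
    if not rows:
        return pd.DataFrame(columns=otu_table.sample_ids, dtype=float)
    summary = pd.DataFrame(rows).T
    summary = summary.loc[summary.sum(axis=1) > 0]
    return summary.astype(float)


def compute_coverage(
    otu_table: OtuTable, hits: HitTable, min_identity: float = 97.0
) -> tuple[dict[str, CoverageLog], CoverageLog]:
    """FTU/FSU per sample plus a dataset-level summary over all OTUs.

    Per sample, the FTU denominator is the set of OTUs with nonzero count in
    that sample; FSU is computed on the same sample's read counts. A sample
    with zero total reads gets NaN markers. The dataset-level log counts
    every OTU in the table once and pools reads across samples.
    """
    assignment = _passing_otus(hits, min_identity)
    per_sample: dict[str, CoverageLog] = {}
    for sample in otu_table.sample_ids:
        col = otu_table.counts[sample]
        present = col[col > 0]
        total_reads = float(present.sum())
        n_total = int(len(present))
        if n_total == 0 or total_reads == 0:
            per_sample[sample] = CoverageLog(float("nan"), float("nan"), 0, n_total)
            continue
        unused = [oid for oid in present.index if oid not in assignment]
        n_used = n_total - len(unused)
        unused_reads = float(present.loc[unused].sum())
        per_sample[sample] = CoverageLog(
            ftu=len(unused) / n_total,
            fsu=unused_reads / total_reads,
            n_otus_used=n_used,
            n_otus_total=n_total,
        )
    all_otus = otu_table.otu_ids
    n_used_all = sum(1 for oid in all_otus if oid in assignment)
    total_all = float(otu_table.counts.values.sum())
    unused_reads_all = float(
        otu_table.counts.loc[[oid for oid in all_otus if oid not in assignment]].values.sum()
    )
    dataset = CoverageLog(
        ftu=1.0 - n_used_all / len(all_otus) if all_otus else float("nan"),
        fsu=unused_reads_all / total_all if total_all > 0 else float("nan"),
        n_otus_used=n_used_all,
        n_otus_total=len(all_otus),
    )
    return per_sample, dataset


def make_functional_prediction(
    summarized: pd.DataFrame,
    db: ReferenceDatabase | MergedDatabase,
    coverage: Mapping[str, CoverageLog] | None = None,
    dataset_coverage: CoverageLog | None = None,
) -> FunctionalProfile:
    """Convert a reference x sample summary into per-sample functional profiles.

    Raw KO vector per sample = sum over references of (summarized abundance x
    that reference's association-matrix row); the relative profile scales the
    raw vector to sum 1. Samples with no detected reference are excluded and
    logged.
    """
    if isinstance(db, MergedDatabase):
        assoc_rows = {rid: db.association_row(rid) for rid in summarized.index}
        pathway_map = db.pathway_map
    else:
        unknown = [rid for rid in summarized.index if rid not in db.association_matrix.index]
        if unknown:
            raise ValueError(f"references not in database: {unknown[:5]}")
        assoc_rows = {rid: db.association_matrix.loc[rid] for rid in summarized.index}
        pathway_map = db.pathway_map

    if assoc_rows:
        assoc = pd.DataFrame(assoc_rows).T.fillna(0.0)
    else:
        assoc = pd.DataFrame(dtype=float)

    samples = list(summarized.columns)
    kept: list[str] = []
    raw_rows: list[pd.Series] = []
    for sample in samples:
        col = summarized[sample] if sample in summarized else pd.Series(dtype=float)
        if summarized.empty or float(col.sum()) == 0.0:
            logger.warning("sample %s has no detected reference; excluded from prediction", sample)
            continue
        raw = assoc.mul(col, axis=0).sum(axis=0)
        if float(raw.sum()) == 0.0:
            logger.warning("sample %s maps only to empty profiles; excluded from prediction", sample)
            continue
        kept.append(sample)
        raw_rows.append(raw)

    if kept:
        ko_raw = pd.DataFrame(raw_rows, index=kept)
        ko_relative = ko_raw.div(ko_raw.sum(axis=1), axis=0)
    else:
        ko_raw = pd.DataFrame(dtype=float)
        ko_relative = pd.DataFrame(dtype=float)

    pathways = sorted({pw for pws in pathway_map.values() for pw in pws})
    pathway_relative = pd.DataFrame(0.0, index=ko_relative.index, columns=pathways)
    for ko in ko_relative.columns:
        for pw in pathway_map.get(ko, ()):  # a KO in k pathways contributes to each
            pathway_relative[pw] += ko_relative[ko]

    return FunctionalProfile(
        ko_relative=ko_relative,
        ko_raw=ko_raw,
        pathway_relative=pathway_relative,
        coverage=dict(coverage or {}),
        dataset_coverage=dataset_coverage,
    )


def predict_functional_profiles(
    otu_table: OtuTable,
    hits: HitTable,
    db: ReferenceDatabase | MergedDatabase,
    min_identity: float = 97.0,
) -> FunctionalProfile:
    """End-to-end convenience: summarize, compute coverage, predict."""
    summarized = summarize_by_reference(otu_table, hits, min_identity)
    coverage, dataset_coverage = compute_coverage(otu_table, hits, min_identity)
    return make_functional_prediction(summarized, db, coverage, dataset_coverage)


def write_coverage_log(path: str | Path, coverage: Mapping[str, CoverageLog], dataset: CoverageLog | None = None) -> None:
    with atomic_open(path) as fh:
        for sample in coverage:
            fh.write(coverage[sample].format_line(sample) + "\n")
        if dataset is not None:
            fh.write(dataset.format_line("DATASET") + "\n")
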