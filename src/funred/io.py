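"""Readers and writers for the plain-text formats used across the package.

All tables are tab-separated text, trees are newick, and sequences are FASTA.
Writes are atomic (temporary file + rename) so an interrupted run never leaves
a half-written output behind, and numbers are serialized with 6 significant
digits so reruns with the same seed produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("funred")

FLOAT_FORMAT = "%.6g"


@contextmanager
def atomic_open(path: str | os.PathLike, mode: str = "w") -> Iterator:
    """Open a temporary file next to *path* and rename it into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Record ids are truncated at the first whitespace; sequences are uppercased
    and RNA (U) is converted to DNA (T). Duplicate ids are an error; an empty
    file yields an empty list with a warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, _normalize_sequence(str(rec.seq))))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with atomic_open(path) as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a labelled numeric matrix: header row, label column, tab-separated.

    Ragged rows and non-numeric cells raise ``ValueError`` with row/column
    context. The leading ``#`` of a ``#OTU_ID``-style label column is kept.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV matrix {path}: {exc}") from exc
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            ) from None
    if out.isna().any().any():
        r, c = next(
            (r, c) for r in out.index for c in out.columns if pd.isna(out.at[r, c])
        )
        raise ValueError(f"missing cell in {path} at row {r!r}, column {c!r}")
    out.index.name = df.index.name
    return out


def write_matrix_tsv(path: str | os.PathLike, matrix: pd.DataFrame, index_label: str | None = None) -> None:
    with atomic_open(path) as fh:
        matrix.to_csv(
            fh, sep="\t", float_format=FLOAT_FORMAT,
            index_label=index_label or matrix.index.name or "id",
        )


def read_otu_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an OTU x sample count table whose first column is ``#OTU_ID``."""
    table = read_matrix_tsv(path)
    if (table.values < 0).any():
        raise ValueError(f"negative counts in OTU table {path}")
    return table


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return tree


def write_tree(path: str | os.PathLike, tree: dendropy.Tree) -> None:
    with atomic_open(path) as fh:
        fh.write(
            tree.as_string(
                schema="newick", unquoted_underscores=True, suppress_rooting=True
            )
        )


def read_pathway_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column ``ko_id<TAB>pathway_id`` file into KO -> {pathways}."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            ko, pw = parts
            if lineno == 1 and (ko, pw) == ("ko_id", "pathway_id"):
                continue  # header row
            mapping.setdefault(ko, set()).add(pw)
    return mapping


def write_pathway_map(path: str | os.PathLike, mapping: dict[str, set[str]]) -> None:
    with atomic_open(path) as fh:
        fh.write("ko_id\tpathway_id\n")
        for ko in sorted(mapping):
            for pw in sorted(mapping[ko]):
                fh.write(f"{ko}\t{pw}\n")


def read_json(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path: str | os.PathLike, obj: dict) -> None:
    with atomic_open(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
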