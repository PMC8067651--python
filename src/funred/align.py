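"""Pairwise nucleotide identity under a semi-global alignment.

Identity is defined as matched columns / aligned columns where terminal gaps
are free (16S fragments are typically subsequences of full-length references)
and internal gaps count as non-matching columns. The alignment path comes
from edlib (banded Myers bit-vector algorithm); with sequences of equal
length edit-distance-optimal and free-end-gap-optimal alignments coincide for
substitution-dominated divergence, and for unequal lengths the shorter
sequence is aligned in infix mode so the longer sequence's overhangs are
free.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_OP.findall(cigar)]


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two nucleotide sequences, in [0, 100].

    Symmetric and deterministic: the pair is aligned in a canonical order
    (shorter sequence as the infix query; lexicographic tie-break at equal
    length).

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 100.0
    if len(a) == len(b):
        query, target = (a, b) if a <= b else (b, a)
        mode = "NW"
    else:
        query, target = (a, b) if len(a) < len(b) else (b, a)
        mode = "HW"
    result = edlib.align(query, target, mode=mode, task="path")
    ops = _cigar_ops(result["cigar"])
    # terminal gaps are free: trim leading/trailing indel runs
    start = 0
    end = len(ops)
    while start < end and ops[start][1] in "ID":
        start += 1
    while end > start and ops[end - 1][1] in "ID":
        end -= 1
    core = ops[start:end]
    columns = sum(n for n, _ in core)
    if columns == 0:
        return 0.0
    matches = sum(n for n, op in core if op == "=")
    return 100.0 * matches / columns
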