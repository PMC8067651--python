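"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (edlib, dendropy
distance matrices, vectorized accumulation): identity comes from a plain
dynamic-programming aligner, clustering from a literal re-reading of the
greedy scheme on top of that aligner, patristic distances from Dijkstra on
an explicit node graph, and profiles from per-cell loops.
"""

from __future__ import annotations

import itertools

import networkx as nx


def dp_identity(a: str, b: str) -> float:
    """Percent identity from an overlap alignment with free terminal gaps.

    Full O(nm) dynamic program maximizing match=+1 / mismatch=-1 / gap=-1
    with free gaps at either end of either sequence, then a traceback;
    identity = matches / aligned columns (internal gaps count as columns,
    terminal overhangs do not).
    """
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]  # free leading gaps
    for i in range(1, n + 1):
        row = score[i]
        prev = score[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if ai == b[j - 1] else -1)
            row[j] = max(diag, prev[j] - 1, row[j - 1] - 1)
    # free trailing gaps: best end point anywhere on the last row/column
    best = max(
        [(score[n][j], n, j) for j in range(m + 1)]
        + [(score[i][m], i, m) for i in range(n + 1)]
    )
    _, i, j = best
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        diag = score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
        if score[i][j] == diag:
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] - 1:
            columns += 1  # internal gap column
            i -= 1
        else:
            columns += 1
            j -= 1
    return 100.0 * matches / columns if columns else 0.0


def brute_cluster(sequences, threshold, identity=dp_identity):
    """Greedy length-sorted centroid clustering, re-implemented literally.

    Returns a list of lists of sequence ids (cluster members in join order),
    using the same ordering and tie rules as the package: longest first,
    length ties lexicographic by id, join the first centroid at or above the
    threshold.
    """
    ordered = sorted(sequences, key=lambda r: (-len(r[1]), r[0]))
    centroids: list[tuple[str, str]] = []
    members: list[list[str]] = []
    for sid, seq in ordered:
        for k, (_, cseq) in enumerate(centroids):
            if identity(seq, cseq) >= threshold * 100.0 - 1e-9:
                members[k].append(sid)
                break
        else:
            centroids.append((sid, seq))
            members.append([sid])
    return members


def tree_graph(tree):
    """dendropy tree -> networkx graph of nodes weighted by branch length."""
    graph = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.head_node is not None:
            graph.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0)
    return graph


def dijkstra_patristic(tree, label_a: str, label_b: str) -> float:
    """Patristic distance as a shortest path over the explicit node graph."""
    graph = tree_graph(tree)
    nodes = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    return nx.dijkstra_path_length(graph, nodes[label_a], nodes[label_b])


def brute_mean_pairwise(tree, labels) -> float:
    labels = sorted(set(labels))
    if len(labels) <= 1:
        return 0.0
    pairs = list(itertools.combinations(labels, 2))
    return sum(dijkstra_patristic(tree, a, b) for a, b in pairs) / len(pairs)


def brute_fri(tree, presence: dict[str, set[str]], ko: str, variant: str = "rfri") -> float:
    """Literal evaluation of the redundancy-index formula for one function."""
    members = sorted(presence)
    possessing = [m for m in members if ko in presence[m]]
    if len(possessing) <= 1:
        return 0.0
    raw = brute_mean_pairwise(tree, possessing) * len(possessing) / len(members)
    if variant == "rfri":
        denom = brute_mean_pairwise(tree, members)
    else:
        denom = brute_mean_pairwise(tree, [l.taxon.label for l in tree.leaf_node_iter()])
    return raw / denom if denom > 0 else 0.0


def brute_association(genomes, threshold, mode="scaled_mean", identity=dp_identity):
    """Recompute every association-matrix and presence-fraction cell from scratch.

    ``genomes`` are GenomeRecord-like objects. Returns
    ``(abundance, presence)`` as nested dicts ``ref_id -> ko -> value``.
    """
    seqs = [
        (f"{g.genome_id}|{i}", s)
        for g in genomes
        for i, s in enumerate(g.ssu_sequences, start=1)
    ]
    clusters = brute_cluster(seqs, threshold, identity=identity)
    by_id = {g.genome_id: g for g in genomes}
    abundance: dict[str, dict[str, float]] = {}
    presence: dict[str, dict[str, float]] = {}
    for member_ids in clusters:
        centroid = member_ids[0]
        copies: dict[str, int] = {}
        for sid in member_ids:
            gid = sid.rsplit("|", 1)[0]
            copies[gid] = copies.get(gid, 0) + 1
        n_genomes = len(copies)
        denom = n_genomes if mode == "scaled_mean" else sum(copies.values())
        kos = sorted({ko for gid in copies for ko in by_id[gid].ko_counts})
        abundance[centroid] = {}
        presence[centroid] = {}
        for ko in kos:
            total = 0.0
            n_with = 0
            for gid, cop in copies.items():
                g = by_id[gid]
                count = g.ko_counts.get(ko, 0)
                total += cop * count / g.n_ssu
                if count > 0:
                    n_with += 1
            presence[centroid][ko] = n_with / n_genomes
            if total > 0:
                abundance[centroid][ko] = total / denom
    return abundance, presence
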