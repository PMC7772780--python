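"""Independent reference implementations used to check the package.

Everything here is deliberately written by a different route than the
library code: graph closure instead of linear scans, explicit per-ATG
translation instead of frame bookkeeping, direct rule transcription for
the breadth classes, and the closed-form normalization map evaluated
from its algebraic definition.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

STOPS = {"TAA", "TAG", "TGA"}


def brute_single_linkage(positions, max_dist):
    """Cluster integer positions by transitive distance <= max_dist.

    Builds the full pairwise adjacency graph and takes connected
    components; returns a sorted list of sorted position tuples.
    """
    pos = np.asarray(sorted(positions))
    n = len(pos)
    if n == 0:
        return []
    diff = np.abs(pos[:, None] - pos[None, :]) <= max_dist
    _, labels = connected_components(csr_matrix(diff), directed=False)
    clusters = {}
    for p, lab in zip(pos, labels):
        clusters.setdefault(lab, []).append(int(p))
    return sorted(tuple(sorted(c)) for c in clusters.values())


def brute_quantile_positions(positions, tpms, q_low, q_up):
    """Running-sum quantile positions, computed with plain Python."""
    total = sum(tpms)
    cum = 0.0
    q_low_pos = q_high_pos = None
    for p, t in zip(positions, tpms):
        cum += t
        if q_low_pos is None and cum >= q_low * total - 1e-9:
            q_low_pos = p
        if q_high_pos is None and cum >= q_up * total - 1e-9:
            q_high_pos = p
    return q_low_pos, q_high_pos


def brute_breadth(values, median_floor=0.2, fold=10.0):
    """Direct transcription of the three-branch breadth rule."""
    vs = sorted(values)
    n = len(vs)
    med = vs[n // 2] if n % 2 else (vs[n // 2 - 1] + vs[n // 2]) / 2
    if med < median_floor:
        return "non_ubiquitous"
    if max(vs) > fold * med:
        return "ubiquitous_nonuniform"
    return "ubiquitous_uniform"


def brute_uorfs(leader, downstream=""):
    """Every ATG starting in the leader, translated codon by codon."""
    full = leader + downstream
    out = []
    for i in range(len(leader)):
        if full[i : i + 3] != "ATG":
            continue
        aa = 0
        has_stop = False
        j = i
        while j + 3 <= len(full):
            codon = full[j : j + 3]
            if codon in STOPS:
                has_stop = True
                break
            aa += 1
            j += 3
        out.append((i, aa, has_stop))
    return out


def brute_longest_orf(seq):
    """Enumerate every (ATG, in-frame stop) pair; return the longest.

    Returns (start, nt_length_including_stop) or None; ties to most 5'.
    """
    best = None
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOPS:
                length = j + 3 - i
                if best is None or length > best[1]:
                    best = (i, length)
                break
    return best


def closed_form_norm(x, alpha_s, c_s, alpha_ref, c_ref):
    """z(x) = (c_s x^-alpha_s / c_ref)^(-1/alpha_ref), written directly."""
    return (c_s * x ** (-alpha_s) / c_ref) ** (-1.0 / alpha_ref)


def random_additive_tree(n_taxa, rng):
    """Random binary unrooted tree topology with positive branch lengths.

    Returns (splits, distance matrix, taxa).  Built by sequential leaf
    attachment on a growing edge list; distances are leaf-to-leaf path
    sums, hence exactly additive.
    """
    taxa = [f"T{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); internal nodes negative ids
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    def drop_edge(a, b):
        edges[a] = [(x, w) for x, w in edges[a] if x != b]
        edges[b] = [(x, w) for x, w in edges[b] if x != a]

    next_internal = [-1]
    add_edge(taxa[0], taxa[1], float(rng.uniform(0.1, 1.0)))
    if n_taxa > 2:
        # third leaf splits the first edge
        mid = next_internal[0]
        next_internal[0] -= 1
        w = edges[taxa[0]][0][1]
        drop_edge(taxa[0], taxa[1])
        add_edge(taxa[0], mid, w / 2)
        add_edge(taxa[1], mid, w / 2)
        add_edge(taxa[2], mid, float(rng.uniform(0.1, 1.0)))
    for leaf in taxa[3:]:
        pairs = [(a, b) for a in edges for b, _ in edges[a] if str(a) < str(b)]
        a, b = pairs[rng.integers(len(pairs))]
        w = dict(edges[a])[b]
        mid = next_internal[0]
        next_internal[0] -= 1
        drop_edge(a, b)
        f = rng.uniform(0.2, 0.8)
        add_edge(a, mid, w * f)
        add_edge(b, mid, w * (1 - f))
        add_edge(leaf, mid, float(rng.uniform(0.1, 1.0)))

    # all-pairs path lengths by BFS/DFS from each leaf
    import heapq

    def dists_from(src):
        dist = {src: 0.0}
        heap = [(0.0, 0, src)]
        counter = 1
        while heap:
            d, _, u = heapq.heappop(heap)
            for v, w in edges[u]:
                nd = d + w
                if v not in dist or nd < dist[v] - 1e-15:
                    dist[v] = nd
                    heap.append((nd, counter, v))
                    counter += 1
        return dist

    n = len(taxa)
    d = np.zeros((n, n))
    for i, t in enumerate(taxa):
        dist = dists_from(t)
        for j, u in enumerate(taxa):
            d[i, j] = dist[u]

    # splits: remove each internal edge, collect leaf side
    anchor = min(taxa)
    splits = set()
    internals = [k for k in edges if isinstance(k, int)]
    for a in internals:
        for b, _ in edges[a]:
            if not isinstance(b, int):
                continue
            # leaves reachable from b without passing a
            seen = {a, b}
            stack = [b]
            side = set()
            while stack:
                u = stack.pop()
                for v, _ in edges[u]:
                    if v in seen:
                        continue
                    seen.add(v)
                    if isinstance(v, int):
                        stack.append(v)
                    else:
                        side.add(v)
            if 2 <= len(side) <= n - 2:
                if anchor in side:
                    side = set(taxa) - side
                splits.add(frozenset(side))
    return splits, d, taxa


def greedy_match(planted_centers, recovered_positions, tol):
    """Hand-coded nearest-first one-to-one matcher; returns index pairs."""
    cand = []
    for i, c in enumerate(planted_centers):
        for j, p in enumerate(recovered_positions):
            if abs(c - p) <= tol:
                cand.append((abs(c - p), i, j))
    cand.sort()
    used_i, used_j, out = set(), set(), []
    for d, i, j in cand:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        out.append((i, j))
    return sorted(out)
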