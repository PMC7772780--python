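"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

Alignments (protein or nucleotide) are consumed, never computed, here.
Distances are proportions of mismatched sites over gap-free column pairs,
optionally Poisson-corrected (-ln(1 - p)).  Trees are built with the
Saitou-Nei neighbor-joining algorithm and split support is estimated by
bootstrap resampling of alignment columns.  Trees are Biopython
``Bio.Phylo`` objects, so Newick round-tripping uses the standard
machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap pseudo-alignment: sample columns with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(taxa=list(self.taxa), rows=rows)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")


GAP_CHARS = set("-.?")


def p_distance(aln: Alignment, poisson_correct: bool = False) -> DistanceMatrix:
    """Pairwise mismatch proportions over columns where neither row is gapped.

    With ``poisson_correct`` the distance is -ln(1 - p), the Poisson
    multiple-hit correction.  A pair with no comparable columns is an error.
    """
    if len(aln.taxa) < 2:
        raise ValueError("need >= 2 taxa")
    n = len(aln.taxa)
    d = np.zeros((n, n))
    rows = [r.upper() for r in aln.rows]
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            p = mismatch / comparable
            if poisson_correct:
                if p >= 1.0:
                    raise ValueError("saturated distance: p = 1 cannot be corrected")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=list(aln.taxa), d=d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; returns an unrooted Bio.Phylo tree.

    Pairs minimizing the Q-criterion are joined iteratively; Q ties are
    broken toward the lexicographically first taxon pair (internal nodes
    sort by the smallest leaf label beneath them).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister
    branch, preserving path lengths.  The returned tree is rooted at the
    final trifurcation for representation only.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa for a tree")
    nodes = [Clade(name=t) for t in dm.taxa]
    keys = list(dm.taxa)  # smallest leaf label beneath each active node
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].branch_length = max(li, 0.0)
        nodes[j].branch_length = max(lj, 0.0)
        new = Clade(clades=[nodes[i], nodes[j]])
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for idx, length in zip((a, b, c), (la, lb, lc)):
        nodes[idx].branch_length = max(length, 0.0)
    root = Clade(clades=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, rooted=False)


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge splits the taxa in two; the side not containing
    the alphabetically first taxon represents the split.
    """
    taxa = sorted(t.name for t in tree.get_terminals())
    anchor = taxa[0]
    all_taxa = set(taxa)
    splits = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = {t.name for t in clade.get_terminals()}
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        if anchor in side:
            side = all_taxa - side
        splits.add(frozenset(side))
    return splits


def bootstrap_support(aln: Alignment, B: int = 100, seed: int = 0,
                      poisson_correct: bool = False) -> Tree:
    """NJ tree with bootstrap split supports from B column resamples.

    Support of each internal split of the full-alignment tree is the
    percentage of replicate trees containing that split.  One seeded
    generator drives all replicates, so identical (alignment, B, seed)
    reproduce identical supports.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree = nj_tree(p_distance(aln, poisson_correct))
    counts: dict[frozenset, int] = {s: 0 for s in tree_splits(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        rep = aln.resample_columns(rng)
        rep_splits = tree_splits(nj_tree(p_distance(rep, poisson_correct)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    taxa_all = {t.name for t in tree.get_terminals()}
    anchor = min(taxa_all)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = {t.name for t in clade.get_terminals()}
        if len(side) < 2 or len(side) > len(taxa_all) - 2:
            continue
        key = frozenset(taxa_all - side if anchor in side else side)
        clade.confidence = 100.0 * counts[key] / B
    return tree


def to_newick(tree: Tree) -> str:
    """Serialize to Newick; internal confidences become node labels."""
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> Tree:
    return Phylo.read(io.StringIO(text), "newick")
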