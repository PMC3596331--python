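"""Distance phylogenetics: p-distance, complete deletion, NJ, bootstrap.

Mirrors the classic MEGA-style protein tree recipe: columns containing a
gap in any sequence are removed (complete deletion), pairwise distance is
the raw proportion of differing sites (p-distance), the tree is built by
Saitou-Nei neighbour joining, and internal-edge support is the percentage
of column-resampled replicates containing the same bipartition.

Alignment construction itself (ClustalX/MUSCLE) is out of scope: this
module ingests already-aligned FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned rows over residues plus the gap symbol."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows must correspond")
        if len(self.labels) < 2:
            raise ValueError("an alignment needs at least two sequences")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxa labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with the retained site count.

    p-distances additionally lie in [0, 1]; general additive matrices
    (e.g. path-length sums on a tree, used to exercise NJ) need not.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    sites_used: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA (residues plus '-')."""
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(labels=tuple(labels), rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n{row}\n")


def complete_deletion(aln: Alignment) -> Alignment:
    """Drop every column containing a gap in ANY row; idempotent."""
    cols = np.array([list(r) for r in aln.rows])
    keep = ~(cols == GAP).any(axis=0)
    if not keep.any():
        raise ValueError(
            "complete deletion removed every column; pairwise deletion is not supported"
        )
    kept = cols[:, keep]
    return Alignment(labels=aln.labels, rows=tuple("".join(r) for r in kept))


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise proportion of differing sites on a gap-free alignment."""
    if any(GAP in r for r in aln.rows):
        raise ValueError("alignment contains gaps; apply complete_deletion first")
    cols = np.array([list(r) for r in aln.rows])
    n, L = cols.shape
    if L == 0:
        raise ValueError("alignment has zero columns")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.mean(cols[i] != cols[j])
            mat[i, j] = mat[j, i] = d
    assert np.all(mat <= 1.0)
    return DistanceMatrix(labels=aln.labels, matrix=mat, sites_used=L)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp negative branch lengths to 0, moving the deficit to the sibling."""
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; exact on additive matrices.

    Ties in the Q-criterion go to the lowest index pair, negative branch
    lengths are clamped to zero with the deficit moved to the sibling
    edge.  Returns an unrooted dendropy tree whose leaf path lengths
    reproduce an additive input matrix to ~1e-9.
    """
    if len(dist.labels) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = dist.matrix.astype(float).copy()
    if np.any(D < 0):
        raise ValueError("negative distances")
    nodes: list[str] = list(dist.labels)

    while len(nodes) > 3:
        n = len(D)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(n, k=1)
        flat = np.full_like(Q, np.inf)
        flat[iu] = Q[iu]
        i, j = np.unravel_index(np.argmin(flat), Q.shape)  # row-major: lowest pair
        la = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lb = D[i, j] - la
        la, lb = _clamp_pair(la, lb)
        merged = f"({nodes[i]}:{la:.12g},{nodes[j]}:{lb:.12g})"
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [merged]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max((d01 + d02 - d12) / 2.0, 0.0)
    l1 = max((d01 + d12 - d02) / 2.0, 0.0)
    l2 = max((d02 + d12 - d01) / 2.0, 0.0)
    newick = f"({nodes[0]}:{l0:.12g},{nodes[1]}:{l1:.12g},{nodes[2]}:{l2:.12g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _internal_bitmasks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    masks = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None:
            continue
        masks.add(edge.bipartition.split_bitmask)
    return masks


def bootstrap(
    aln: Alignment, replicates: int = 1000, seed: int = 0
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap percentages on internal edges.

    Each replicate resamples columns with replacement, reruns complete
    deletion, p-distance and NJ, and every internal bipartition of the
    full-data tree is scored by the percentage of replicates containing
    it (stored as the internal node label and ``node.support``).
    Deterministic for a given seed.
    """
    if replicates < 1:
        raise ValueError("at least one replicate is required")
    rng = np.random.default_rng(seed)
    full = nj_tree(p_distance(complete_deletion(aln)))
    namespace = full.taxon_namespace
    counts: dict[int, int] = {}
    cols = np.array([list(r) for r in aln.rows])
    for _ in range(replicates):
        idx = rng.integers(0, aln.n_columns, size=aln.n_columns)
        rep_rows = tuple("".join(row) for row in cols[:, idx])
        rep_aln = Alignment(labels=aln.labels, rows=rep_rows)
        try:
            rep_tree = nj_tree(p_distance(complete_deletion(rep_aln)))
        except ValueError:  # all resampled columns gapped
            continue
        rep_tree = dendropy.Tree.get(
            data=rep_tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=namespace,
        )
        rep_tree.is_rooted = False
        for mask in _internal_bitmasks(rep_tree):
            counts[mask] = counts.get(mask, 0) + 1
    full.encode_bipartitions()
    for edge in full.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None:
            continue
        support = 100.0 * counts.get(edge.bipartition.split_bitmask, 0) / replicates
        head.label = f"{support:g}"
        head.support = support
    return full


def topology_recovery(true_tree: dendropy.Tree, inferred: dendropy.Tree) -> float:
    """Fraction of the true tree's internal bipartitions present in the
    inferred tree (1.0 = identical unrooted topology)."""
    namespace = dendropy.TaxonNamespace()

    def _reload(t: dendropy.Tree) -> dendropy.Tree:
        out = dendropy.Tree.get(
            data=t.as_string(schema="newick"), schema="newick", taxon_namespace=namespace
        )
        out.is_rooted = False
        return out

    true_masks = _internal_bitmasks(_reload(true_tree))
    if not true_masks:
        return 1.0
    inferred_masks = _internal_bitmasks(_reload(inferred))
    return len(true_masks & inferred_masks) / len(true_masks)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Newick with supports as internal labels, 6-decimal branch lengths."""
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
    )
    Path(path).write_text(text)


def write_distance_tsv(dist: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP-style square matrix as TSV."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist.labels)}\n")
        for label, row in zip(dist.labels, dist.matrix):
            fh.write(label + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
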