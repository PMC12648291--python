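"""Split-half phylogenetics: the internal-symmetry statistic for ferredoxins.

The two beta-alpha-beta halves of a bacterial ferredoxin descend from an
ancient gene duplication.  How far the halves have diverged since that
duplication can be measured by placing the N- and C-terminal halves of every
protein as separate leaves on one phylogenetic tree and reading off, for each
parent protein, the *cophenetic distance* between its two half-leaves — the
sum of branch lengths (substitutions/site, "tree scale") along the unique
path connecting them.  Internally symmetric proteins (recent duplications,
symdoxin-like) show paired distances near zero; anciently diverged halves
show large distances.

The pipeline implemented here:

1. read an aligned FASTA block of full-length sequences,
2. drop alignment columns with more than 10% gaps,
3. split every row at the alignment midpoint into N and C halves,
4. compute pairwise distances between all half-sequences (p-distance or its
   Poisson correction ``-ln(1 - p)``),
5. build a neighbor-joining tree over the halves (or import an externally
   inferred tree in Newick), and
6. report the per-parent paired cophenetic distance with symmetry flags at
   configurable thresholds (defaults 1 and 2 substitutions/site).

Trees are dendropy ``Tree`` objects throughout, so externally computed
maximum-likelihood trees can be dropped in via Newick without touching the
rest of the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .mining import AMINO_ACIDS

__all__ = [
    "Alignment",
    "HalfPair",
    "DistanceMatrix",
    "SymmetryResult",
    "read_alignment",
    "write_alignment",
    "remove_gappy_columns",
    "split_halves",
    "pairwise_distance",
    "nj_tree",
    "read_newick",
    "write_newick",
    "cophenetic_distance",
    "cophenetic_matrix",
    "paired_symmetry",
    "symmetry_report",
]

GAP = "-"
_ALIGNED_CHARS = AMINO_ACIDS | {GAP}


@dataclass
class Alignment:
    """A gapped, equal-width block of sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        if self.rows:
            width = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise ValueError(
                        f"ragged alignment: row {sid!r} has length {len(row)}, "
                        f"expected {width}"
                    )
                bad = set(row) - _ALIGNED_CHARS
                if bad:
                    raise ValueError(
                        f"row {sid!r} contains non-residue characters {sorted(bad)}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)].replace(GAP, "")


@dataclass(frozen=True)
class HalfPair:
    """Links a parent sequence to its two half-leaves in the split alignment."""

    parent_id: str

    @property
    def n_half_id(self) -> str:
        return self.parent_id + "_N"

    @property
    def c_half_id(self) -> str:
        return self.parent_id + "_C"


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class SymmetryResult:
    parent_id: str
    cophenetic_distance: float
    flags: dict[float, bool] = field(default_factory=dict)

    def symmetric_at(self, threshold: float) -> bool:
        return self.cophenetic_distance < threshold


# ---------------------------------------------------------------------------
# Alignment I/O and column filtering


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; all rows must have equal width."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if rows:
        width = len(rows[0])
        for sid, row in zip(ids, rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment in {path}: row {sid!r} has length "
                    f"{len(row)}, expected {width}"
                )
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def remove_gappy_columns(
    aln: Alignment, max_gap_frac: float = 0.10
) -> tuple[Alignment, dict[int, int]]:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_frac``.

    Returns the filtered alignment and the mapping of retained old column
    indices to new ones.  A column at exactly the threshold is kept.
    """
    if aln.n_rows == 0:
        return aln, {}
    arr = np.array([list(r) for r in aln.rows])
    gap_frac = (arr == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_frac)
    if keep.size == 0:
        raise ValueError("all alignment columns exceed the gap threshold")
    mapping = {int(old): new for new, old in enumerate(keep)}
    rows = ["".join(r) for r in arr[:, keep]]
    return Alignment(ids=list(aln.ids), rows=rows), mapping


SplitSpec = int | tuple[int, int]


def split_halves(
    aln: Alignment,
    split_col: SplitSpec | dict[str, SplitSpec] | None = None,
) -> tuple[Alignment, Alignment, list[HalfPair]]:
    """Split every row into N- and C-terminal halves.

    By default each row is cut at column ``floor(n_cols / 2)``.  For curated
    cases ``split_col`` overrides the cut point: a single integer cuts all
    rows there, an ``(n_end, c_start)`` pair excises the columns in between
    (e.g. an inter-domain linker), and a per-parent mapping assigns either
    form per row (halves are then gap-padded to a common width).  A parent
    whose half contains no residues is excluded with a warning.  Half ids
    carry ``_N`` / ``_C`` suffixes.
    """
    if aln.n_cols < 2:
        raise ValueError("alignment must have at least 2 columns to split")
    default_m = aln.n_cols // 2

    def cut_for(sid: str) -> tuple[int, int]:
        spec: SplitSpec | None
        if isinstance(split_col, dict):
            spec = split_col.get(sid, default_m)
        else:
            spec = split_col
        if spec is None:
            spec = default_m
        if isinstance(spec, tuple):
            n_end, c_start = int(spec[0]), int(spec[1])
        else:
            n_end = c_start = int(spec)
        if not 0 < n_end <= c_start < aln.n_cols:
            raise ValueError(f"split columns ({n_end}, {c_start}) out of range for {sid!r}")
        return n_end, c_start

    n_ids, n_rows, c_ids, c_rows, pairs = [], [], [], [], []
    for sid, row in zip(aln.ids, aln.rows):
        n_end, c_start = cut_for(sid)
        n_part, c_part = row[:n_end], row[c_start:]
        if not n_part.replace(GAP, "") or not c_part.replace(GAP, ""):
            warnings.warn(
                f"parent {sid!r} excluded: one half degaps to an empty sequence",
                stacklevel=2,
            )
            continue
        pair = HalfPair(parent_id=sid)
        n_ids.append(pair.n_half_id)
        n_rows.append(n_part)
        c_ids.append(pair.c_half_id)
        c_rows.append(c_part)
        pairs.append(pair)
    # pad to common width (only needed with per-parent split columns)
    for block in (n_rows, c_rows):
        w = max((len(r) for r in block), default=0)
        for i, r in enumerate(block):
            block[i] = r + GAP * (w - len(r))
    return (
        Alignment(ids=n_ids, rows=n_rows),
        Alignment(ids=c_ids, rows=c_rows),
        pairs,
    )


def stack_halves(aln_n: Alignment, aln_c: Alignment) -> Alignment:
    """Stack the N- and C-half blocks into one alignment over all halves.

    Column *i* of the N block is treated as homologous to column *i* of the
    C block — the premise of the internal-symmetry comparison, valid because
    the two halves of the fold are a tandem repeat.  The narrower block is
    padded with trailing gap columns.
    """
    width = max(aln_n.n_cols, aln_c.n_cols)
    rows = [r + GAP * (width - len(r)) for r in aln_n.rows + aln_c.rows]
    return Alignment(ids=aln_n.ids + aln_c.ids, rows=rows)


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def pairwise_distance(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """All-pairs evolutionary distance between alignment rows.

    ``p``: mismatch fraction over columns where both rows are ungapped.
    ``poisson``: the correction ``-ln(1 - p)`` for multiple hits.
    A pair with no comparable columns, or ``p >= 1`` under the Poisson
    model, is an error.
    """
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows to compute distances")
    arr = np.array([list(r) for r in aln.rows])
    ungapped = arr != GAP
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise ValueError(
                    f"rows {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "ungapped columns"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / n_comp
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"rows {aln.ids[i]!r} and {aln.ids[j]!r}: p-distance "
                        ">= 1, Poisson correction undefined"
                    )
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=list(aln.ids), values=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou–Nei agglomeration: at each step the pair minimising
    Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined, with branch lengths from the
    two-decomposition formulas.  Negative estimated branch lengths are
    clamped to zero.  Ties in Q are broken by the lexicographically smallest
    (label_i, label_j) pair, so the result is deterministic.  The returned
    tree is unrooted (trifurcation at the final join).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # sort key per active node: smallest leaf label underneath, for tie-breaks
    keys = list(dm.labels)
    d = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
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
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0).reshape(-1, 1)])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        new_index = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    # resolve the final three nodes around a central (unrooted) vertex
    i, j, k = active
    center = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        length = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
        center.add_child(nodes[a])
        nodes[a].edge.length = length
    tree.seed_node = center
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# Newick I/O and cophenetic distances


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree file (branch lengths preserved)."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def _leaf_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise KeyError(f"leaf {label!r} not found in tree")


def cophenetic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    if a == b:
        _leaf_node(tree, a)
        return 0.0
    na, nb = _leaf_node(tree, a), _leaf_node(tree, b)
    # cumulative distance from `a` up to each of its ancestors
    ancestors: dict[int, float] = {}
    node, dist = na, 0.0
    while node is not None:
        ancestors[id(node)] = dist
        dist += node.edge.length or 0.0
        node = node.parent_node
    node, dist = nb, 0.0
    while node is not None:
        if id(node) in ancestors:
            return ancestors[id(node)] + dist
        dist += node.edge.length or 0.0
        node = node.parent_node
    raise ValueError(f"leaves {a!r} and {b!r} are not connected")


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs path-length matrix over the tree's leaves."""
    labels = sorted(
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon
    )
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = cophenetic_distance(tree, labels[i], labels[j])
    return DistanceMatrix(labels=labels, values=d)


def paired_symmetry(
    tree: dendropy.Tree,
    pairs: list[HalfPair],
    thresholds: tuple[float, ...] = (1.0, 2.0),
) -> tuple[list[SymmetryResult], float]:
    """Per-parent cophenetic distance between the N- and C-half leaves.

    Returns one result per parent (with a symmetry flag ``distance <
    threshold`` for every requested threshold) plus the collection mean.
    """
    results: list[SymmetryResult] = []
    for pair in pairs:
        try:
            dist = cophenetic_distance(tree, pair.n_half_id, pair.c_half_id)
        except KeyError as exc:
            raise KeyError(
                f"parent {pair.parent_id!r}: half leaf missing from tree ({exc})"
            ) from exc
        results.append(
            SymmetryResult(
                parent_id=pair.parent_id,
                cophenetic_distance=dist,
                flags={t: dist < t for t in thresholds},
            )
        )
    mean = float(np.mean([r.cophenetic_distance for r in results])) if results else math.nan
    return results, mean


def symmetry_report(results: list[SymmetryResult]) -> pd.DataFrame:
    """Tabulate symmetry results with flags at the standard thresholds."""
    return pd.DataFrame(
        {
            "parent_id": [r.parent_id for r in results],
            "cophenetic_distance": [r.cophenetic_distance for r in results],
            "flag_lt1": [r.symmetric_at(1.0) for r in results],
            "flag_lt2": [r.symmetric_at(2.0) for r in results],
        }
    )
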