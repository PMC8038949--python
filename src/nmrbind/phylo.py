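"""Pairwise sequence identity, p-distances, neighbor joining and bootstrap.

The distance stage of a protein-family analysis: percent identity between
homologous sequences (aligned columns or an on-the-fly Needleman-Wunsch
global alignment), uncorrected p-distances with pairwise gap deletion, the
Saitou-Nei neighbor-joining algorithm with deterministic tie-breaking, and
nonparametric bootstrap supports (column resampling) mapped onto the
full-data tree.  Trees are scikit-bio ``TreeNode`` objects and round-trip
through Newick with branch lengths and integer supports as internal labels.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "Alignment",
    "read_fasta",
    "write_fasta",
    "percent_identity",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "write_newick",
    "read_newick",
]

GAP = "-"
AMBIGUOUS = set("XBZ")


@dataclass
class Alignment:
    """A set of equal-length aligned protein sequences with unique ids."""

    ids: list
    seqs: list

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have the same length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def columns(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, size=self.length)
        return Alignment(list(self.ids),
                         ["".join(s[j] for j in cols) for s in self.seqs])


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(alignment: Alignment, path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(alignment.ids, alignment.seqs)]
    SeqIO.write(records, str(path), "fasta")


def _identity_over_pairs(a: str, b: str) -> float:
    matches = total = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        if x in AMBIGUOUS or y in AMBIGUOUS:
            continue  # ambiguity codes drop out of the denominator
        total += 1
        if x == y:
            matches += 1
    if total == 0:
        raise ValueError("no comparable non-gap columns")
    return 100.0 * matches / total


def percent_identity(seq_a: str, seq_b: str, mode: str = "aligned",
                     match: float = 1.0, mismatch: float = 0.0,
                     gap: float = -1.0) -> float:
    """Percent identity between two protein sequences.

    ``aligned`` treats the inputs as rows of one alignment and counts
    identical pairs over columns where both are non-gap; ``global_align``
    first builds a Needleman-Wunsch global alignment (default scoring:
    match +1, mismatch 0, gap -1).  Case-insensitive; ambiguous residues
    (X/B/Z) are excluded from the denominator.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    if mode == "aligned":
        if len(a) != len(b):
            raise ValueError("aligned mode requires equal-length sequences")
        return _identity_over_pairs(a, b)
    if mode == "global_align":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        aln = aligner.align(a.replace(GAP, ""), b.replace(GAP, ""))[0]
        return _identity_over_pairs(aln[0], aln[1])
    raise ValueError(f"unknown mode {mode!r}")


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise p-distances with pairwise gap deletion.

    The distance between two rows is the fraction of differing sites over
    the columns where both rows are non-gap; a pair with no comparable
    columns is an error.
    """
    if alignment.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    n = alignment.n_seqs
    cols = alignment.columns()
    nongap = cols != GAP
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}")
            diff = int((cols[i][both] != cols[j][both]).sum())
            mat[i, j] = mat[j, i] = diff / total
    return DistanceMatrix(mat, ids=list(alignment.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie handling.

    Joins the pair minimising the Q-criterion
    ``Q_ij = (n - 2) d_ij - r_i - r_j``; exact ties go to the lowest index
    pair.  Negative branch lengths are clamped to 0 with the deficit
    transferred to the adjacent (sister) branch.  Returns an unrooted tree
    represented with a trifurcating root.
    """
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [TreeNode(name=str(i)) for i in dm.ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best, bi, bj = None, -1, -1
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best:
                    best, bi, bj = q, i, j
        li = d[bi, bj] / 2.0 + (r[bi] - r[bj]) / (2.0 * (n - 2))
        lj = d[bi, bj] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[bi], nodes[bj]])
        nodes[bi].length, nodes[bj].length = li, lj
        # distances from the new node to the remainder
        keep = [k for k in range(n) if k not in (bi, bj)]
        new_row = np.array([(d[bi, k] + d[bj, k] - d[bi, bj]) / 2.0 for k in keep])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-node star: closed-form branch lengths
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = [(d01 + d02 - d12) / 2.0,
               (d01 + d12 - d02) / 2.0,
               (d02 + d12 - d01) / 2.0]
    root = TreeNode(children=list(nodes))
    for node, ln in zip(nodes, lengths):
        node.length = max(ln, 0.0)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def bipartitions(tree: TreeNode) -> dict:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented by the frozenset of leaf names on the
    side not containing the lexicographically smallest leaf; maps the
    canonical set to the internal node below the edge.
    """
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = frozenset(leaves) - side
        out[side] = node
    return out


def bootstrap_support(alignment: Alignment, replicates: int = 1000,
                      seed: int | None = None) -> TreeNode:
    """Neighbor-joining tree with nonparametric bootstrap supports.

    Columns are resampled with replacement, the tree is rebuilt per
    replicate, and each internal edge of the full-data tree receives the
    percentage of replicate trees containing the same bipartition
    (``node.support``, 0-100).  Seed-deterministic.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(p_distance(alignment))
    parts = bipartitions(full)
    if len(set(alignment.seqs)) == 1:
        warnings.warn("all sequences identical: no resolved bipartitions; "
                      "supports not assigned")
        return full
    counts = {side: 0 for side in parts}
    for k in range(replicates):
        rep = alignment.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(p_distance(rep))
        except ValueError as exc:
            raise RuntimeError(f"bootstrap replicate {k} failed: {exc}") from exc
        for side in bipartitions(rep_tree):
            if side in counts:
                counts[side] += 1
    for side, node in parts.items():
        node.support = 100.0 * counts[side] / replicates
    return full


def write_newick(tree: TreeNode) -> str:
    """Render a tree as Newick with branch lengths; integer bootstrap
    supports become internal-node labels."""
    copy = tree.copy()
    for node in copy.non_tips(include_self=True):
        support = getattr(node, "support", None)
        if support is not None:
            # skbio's writer emits the support itself as the internal label
            # when the node has no name
            node.support = int(round(support))
            node.name = None
    buf = io.StringIO()
    copy.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse Newick; numeric internal labels are interpreted as supports."""
    tree = TreeNode.read(io.StringIO(text), format="newick")
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
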