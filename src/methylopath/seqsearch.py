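"""Candidate-enzyme sequence triage.

Given a FASTA of candidate protein sequences (e.g. hexulose-phosphate
synthase candidates retrieved from a public search), this module

* computes global pairwise identities under an affine-gap Needleman-Wunsch
  alignment (BLOSUM62, gap open 11 / extend 1 — BLAST-like defaults),
* removes redundancy by greedy length-descending single-linkage-to-
  representative clustering at an identity threshold (BLASTclust-style,
  default 90%),
* builds a neighbour-joining tree from pairwise identity distances
  (raw p-distance 1 - identity; no rate correction), and
* reads/writes Newick.

The external database searches themselves (BLAST, HMMER/Pfam profile
alignment) are outside this module: it consumes any FASTA.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"


class SequenceError(ValueError):
    """Raised on invalid sequences, matrices or tree input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter alphabet (plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - AA_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with its identity fraction.

    identity = matching columns / alignment columns, terminal gap columns
    excluded from the denominator (BLAST-like convention).
    """

    aligned_a: str
    aligned_b: str
    identity: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise SequenceError("aligned strings differ in length")


def read_fasta(path_or_handle) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def _aligner(
    substitution_matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = (
        substitution_matrix
        if substitution_matrix is not None
        else substitution_matrices.load("BLOSUM62")
    )
    aligner.mode = "global"
    # PairwiseAligner charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; a length-L gap then costs
    # gap_open + L*gap_extend, the BLAST convention.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _identity_from_aligned(a: str, b: str, denominator: str = "columns") -> float:
    n = len(a)
    start, end = 0, n
    while start < n and (a[start] == GAP or b[start] == GAP):
        start += 1
    while end > start and (a[end - 1] == GAP or b[end - 1] == GAP):
        end -= 1
    matches = sum(1 for x, y in zip(a[start:end], b[start:end]) if x == y and x != GAP)
    if denominator == "columns":
        denom = end - start
    elif denominator == "shorter":
        denom = min(len(a.replace(GAP, "")), len(b.replace(GAP, "")))
    else:
        raise SequenceError(f"unknown identity denominator {denominator!r}")
    return matches / denom if denom else 0.0


def global_align(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    substitution_matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    identity_denominator: str = "columns",
) -> AlignmentResult:
    """Optimal global alignment under affine gap penalties.

    End gaps are penalised (true global mode).  Ties between co-optimal
    alignments are broken deterministically by taking the aligner's first
    reported alignment; the identity of co-optimal alignments may differ but
    the score is unique.
    """
    sa = a if isinstance(a, ProteinSequence) else ProteinSequence("a", a)
    sb = b if isinstance(b, ProteinSequence) else ProteinSequence("b", b)
    aligner = _aligner(substitution_matrix, gap_open, gap_extend)
    alignment = next(iter(aligner.align(sa.residues, sb.residues)))
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    identity = _identity_from_aligned(aligned_a, aligned_b, identity_denominator)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        identity=identity,
        score=float(alignment.score),
    )


def pairwise_identity(a, b, **kwargs) -> float:
    return global_align(a, b, **kwargs).identity


@dataclass
class Cluster:
    representative: ProteinSequence
    members: list[tuple[ProteinSequence, float]] = field(default_factory=list)

    def member_ids(self) -> list[str]:
        return [self.representative.id] + [s.id for s, _ in self.members]


def cluster_by_identity(
    sequences: Sequence[ProteinSequence],
    threshold: float = 0.90,
    **align_kwargs,
) -> list[Cluster]:
    """Greedy BLASTclust-style redundancy removal.

    Sequences are visited in canonical order (length descending, id as the
    tiebreak); each joins the first existing cluster whose representative it
    matches at >= threshold identity, otherwise it founds a new cluster.
    Deterministic and independent of input order; every sequence lands in
    exactly one cluster.
    """
    if not sequences:
        raise SequenceError("no sequences to cluster")
    if not 0.0 < threshold <= 1.0:
        raise SequenceError("identity threshold must lie in (0, 1]")
    ordered = sorted(sequences, key=lambda s: (-len(s), s.id))
    clusters: list[Cluster] = []
    for seq in ordered:
        for cluster in clusters:
            ident = pairwise_identity(seq, cluster.representative, **align_kwargs)
            if ident >= threshold:
                cluster.members.append((seq, ident))
                break
        else:
            clusters.append(Cluster(representative=seq))
    return clusters


def clusters_to_table(clusters: Sequence[Cluster]):
    import pandas as pd

    rows = []
    for i, cl in enumerate(clusters):
        rows.append(
            {
                "cluster_id": i,
                "representative": cl.representative.id,
                "member": cl.representative.id,
                "identity": 1.0,
            }
        )
        for seq, ident in cl.members:
            rows.append(
                {
                    "cluster_id": i,
                    "representative": cl.representative.id,
                    "member": seq.id,
                    "identity": ident,
                }
            )
    return pd.DataFrame(rows)


# -- distances and trees ---------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise SequenceError("distance matrix shape disagrees with labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise SequenceError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise SequenceError("distance matrix must be nonnegative")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise SequenceError("distance matrix diagonal must be zero")

    def to_skbio(self) -> SkbioDistanceMatrix:
        return SkbioDistanceMatrix(self.d, self.labels)


def identity_distance_matrix(
    sequences: Sequence[ProteinSequence], **align_kwargs
) -> DistanceMatrix:
    """All-pairs p-distance matrix, d = 1 - global identity (uncorrected)."""
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(sequences[i], sequences[j], **align_kwargs)
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(labels=[s.id for s in sequences], d=d)


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Iteratively joins the pair minimising the Q-criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j.  Exact on additive matrices: leaf-to-
    leaf path lengths in the returned (unrooted, trifurcating-rooted) tree
    reproduce the input distances.  Negative branch lengths are clamped to
    zero with the deficit moved to the sibling branch, keeping pair path
    lengths intact.  Ties break on the lexicographically first index pair,
    so the result is deterministic.
    """
    n = len(D.labels)
    if n < 2:
        raise SequenceError("need at least two taxa")
    if n == 2:
        half = D.d[0, 1] / 2.0
        return TreeNode(
            children=[
                TreeNode(name=D.labels[0], length=half),
                TreeNode(name=D.labels[1], length=half),
            ]
        )
    d = D.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    active = list(range(n))

    def clamp(pair: list[float]) -> list[float]:
        a, b = pair
        if a < 0:
            b += a
            a = 0.0
        if b < 0:
            a += b
            b = 0.0
        return [a, max(b, 0.0)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp([li, lj])
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # reuse slot i for the new node, retire slot j
        new_d = {
            k: 0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in active if k not in (i, j)
        }
        for k, v in new_d.items():
            d[i, k] = d[k, i] = max(v, 0.0)
        nodes[i] = parent
        active.remove(j)
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return root


def _format_length(x: float) -> str:
    s = f"{x:.6g}"
    if abs(float(s) - x) > 1e-9:
        s = f"{x:.12g}"
    return s


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to Newick with 6-significant-digit branch lengths
    (more digits only where needed to stay within 1e-9 of the value)."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            base = node.name or ""
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                base += node.name
        if node.length is not None:
            base += f":{_format_length(node.length)}"
        return base

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse Newick text; malformed input raises with a position hint."""
    from io import StringIO

    try:
        return TreeNode.read(StringIO(text), format="newick")
    except Exception as exc:  # skbio NewickFormatError carries the detail
        pos = None
        m = re.search(r"\d+", str(exc))
        if m:
            pos = m.group()
        raise SequenceError(
            f"malformed newick (near {pos or 'unknown position'}): {exc}"
        ) from exc


def robinson_foulds(a: TreeNode, b: TreeNode) -> float:
    """Robinson-Foulds distance (number of discordant bipartitions)."""
    return float(a.compare_rfd(b))
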