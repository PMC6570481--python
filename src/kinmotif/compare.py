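"""Comparing phosphorylation-site motifs across a kinase family.

Kinases are clustered by the Pearson correlation between their motif
vectors (the flattened capped linear matrix, optionally extended with the
phospho-acceptor preference), using average linkage on the one-minus-
Pearson distance.  The same machinery serves percent-identity matrices of
aligned kinase-domain sequences, sequence-logo heights from log2 motifs,
and extraction of residues at fixed offsets from the conserved HRD / APE /
DFG kinase-domain anchors (e.g. HRD+2, APE-4, DFG+1), whose identity
tracks phospho-acceptor specificity across the kinome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import ACCEPTORS, GRID_RESIDUES, POSITIONS
from .errors import (
    AnchorAmbiguityError,
    AnchorNotFoundError,
    DegenerateDataError,
    InputError,
    ParameterError,
)
from .opls import MotifMatrix

#: minimum pairwise-complete cells for a motif correlation (of 198)
DEFAULT_MIN_OVERLAP = 150

GAP = "-"

Anchor = Literal["HRD", "APE", "DFG"]


# ---------------------------------------------------------------------------
# motif vectors and similarity


def motif_vector(motif: MotifMatrix, include_acceptor: bool = True) -> pd.Series:
    """Flatten a capped motif into a deterministic vector.

    Order: positions ascending, residues in the fixed grid alphabet, with
    the acceptor S/T/Y values appended when ``include_acceptor`` is set and
    pools were measured.  Missing cells stay NaN (handled pairwise-complete
    downstream).
    """
    motif.require_stage("capped")
    index = [(pos, res) for pos in POSITIONS for res in GRID_RESIDUES]
    data = [motif.values.at[pos, res] for pos, res in index]
    if include_acceptor and motif.acceptor_pref is not None:
        index += [(0, a) for a in ACCEPTORS]
        data += [motif.acceptor_pref.get(a, np.nan) for a in ACCEPTORS]
    return pd.Series(data, index=pd.MultiIndex.from_tuples(index, names=["position", "residue"]))


@dataclass
class SimilarityMatrix:
    """Symmetric kinase-by-kinase similarity (Pearson r or % identity)."""

    ids: list[str]
    values: pd.DataFrame
    metric_tag: str = "pearson"

    def __post_init__(self) -> None:
        self.values = self.values.loc[self.ids, self.ids].astype(float)
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise InputError("similarity matrix is not symmetric")

    def to_distance(self) -> pd.DataFrame:
        """One-minus-similarity distance (identity matrices are rescaled from %)."""
        if self.metric_tag == "pct_identity":
            return 1.0 - self.values / 100.0
        return 1.0 - self.values


def _pairwise_pearson(a: pd.Series, b: pd.Series, min_overlap: int) -> float:
    mask = a.notna() & b.notna()
    n = int(mask.sum())
    if n < min_overlap:
        raise InputError(
            f"only {n} pairwise-complete cells (< {min_overlap}) between motif vectors"
        )
    x, y = a[mask].to_numpy(), b[mask].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero-variance motif vector; Pearson undefined")
    return float(np.corrcoef(x, y)[0, 1])


def similarity_matrix(
    vectors: Mapping[str, pd.Series], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SimilarityMatrix:
    """Pairwise Pearson correlation between kinase motif vectors."""
    if len(vectors) < 2:
        raise InputError("need at least 2 kinases")
    ids = sorted(vectors)
    index_sets = {k: frozenset(v.index) for k, v in vectors.items()}
    reference = index_sets[ids[0]]
    for k in ids[1:]:
        if index_sets[k] != reference:
            diff = sorted(index_sets[k] ^ reference)
            raise InputError(f"motif vector index mismatch for {k!r}: {diff}")
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            r = _pairwise_pearson(vectors[a], vectors[b], min_overlap)
            mat.at[a, b] = mat.at[b, a] = r
    return SimilarityMatrix(ids=ids, values=mat, metric_tag="pearson")


# ---------------------------------------------------------------------------
# average-linkage clustering


@dataclass
class TreeNode:
    """Binary dendrogram node; ``height`` is the merge distance (leaves: 0)."""

    members: tuple[str, ...]
    height: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_newick(self) -> str:
        return self._newick(parent_height=self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        length = parent_height - self.height
        if self.is_leaf:
            return f"{self.members[0]}:{length:.9g}"
        inner = ",".join(
            child._newick(parent_height=self.height) for child in (self.left, self.right)
        )
        return f"({inner}):{length:.9g}"


@dataclass
class Dendrogram:
    """Average-linkage tree over one-minus-Pearson (or identity) distances."""

    root: TreeNode
    leaf_ids: list[str]
    merge_heights: list[float] = field(default_factory=list)

    def to_newick(self) -> str:
        return self.root.to_newick()

    def root_bipartition(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf sets of the two clusters joined by the final merge."""
        if self.root.is_leaf:
            raise InputError("single-leaf tree has no bipartition")
        return frozenset(self.root.left.members), frozenset(self.root.right.members)


def average_linkage(distance: pd.DataFrame) -> Dendrogram:
    """UPGMA over a symmetric distance matrix with deterministic tie-breaks.

    Inter-cluster distance is the unweighted mean of all pairwise leaf
    distances.  At each step the pair with the smallest distance merges;
    exact ties are broken lexicographically by the pair's smallest member
    ids, so the tree is a pure function of the input.
    """
    ids = list(distance.index)
    if len(ids) < 2:
        raise InputError("need at least 2 leaves to cluster")
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix is not symmetric")
    clusters: dict[int, TreeNode] = {
        i: TreeNode(members=(ids[i],)) for i in range(len(ids))
    }
    sizes = {i: 1 for i in clusters}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in clusters for j in clusters if i < j
    }
    heights: list[float] = []
    next_id = len(ids)
    while len(clusters) > 1:
        # smallest distance; ties by lexicographic (min member, min member)
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(clusters[kv[0][0]].members + clusters[kv[0][1]].members),
                max(
                    min(clusters[kv[0][0]].members), min(clusters[kv[0][1]].members)
                ),
            ),
        )
        (i, j), h = best
        left, right = clusters[i], clusters[j]
        if min(right.members) < min(left.members):
            left, right = right, left
        node = TreeNode(
            members=tuple(sorted(left.members + right.members)),
            height=h,
            left=left,
            right=right,
        )
        heights.append(h)
        new_size = sizes[i] + sizes[j]
        new_dists = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dists[k] = (sizes[i] * dik + sizes[j] * djk) / new_size
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[next_id] = node
        sizes[next_id] = new_size
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    root = next(iter(clusters.values()))
    if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
        raise DegenerateDataError("non-monotone merge heights in average linkage")
    return Dendrogram(root=root, leaf_ids=sorted(ids), merge_heights=heights)


def cluster_kinases(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage clustering on the one-minus-Pearson distance."""
    return average_linkage(sim.to_distance())


# ---------------------------------------------------------------------------
# sequence identity


def sequence_identity_matrix(aligned: Mapping[str, str]) -> SimilarityMatrix:
    """Percent identity between aligned sequences, over mutually ungapped columns."""
    if len(aligned) < 2:
        raise InputError("need at least 2 aligned sequences")
    ids = sorted(aligned)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise InputError(f"aligned sequences differ in length: {sorted(lengths)}")
    mat = pd.DataFrame(100.0 * np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            mat.at[a, b] = mat.at[b, a] = percent_identity(aligned[a], aligned[b])
    return SimilarityMatrix(ids=ids, values=mat, metric_tag="pct_identity")


def percent_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise InputError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        raise DegenerateDataError("no mutually ungapped columns")
    matches = sum(x == y for x, y in pairs)
    return 100.0 * matches / len(pairs)


# ---------------------------------------------------------------------------
# sequence logos


def logo_heights(motif: MotifMatrix, favored_only: bool = False) -> pd.DataFrame:
    """Signed logo heights from a log2 motif: the log2 value itself.

    Positive heights are favored residues (drawn above the axis), negative
    heights disfavored ones (below).  ``favored_only`` zeroes the negative
    heights for logos that show enrichment only.
    """
    motif.require_stage("log2")
    heights = motif.values.copy()
    if favored_only:
        heights = heights.clip(lower=0.0)
    return heights


# ---------------------------------------------------------------------------
# kinase-domain anchors


@dataclass(frozen=True)
class AnchorResidueReport:
    """Residue at a fixed offset from a conserved kinase-domain anchor.

    Offsets follow field usage: negative offsets count N-terminal with the
    anchor's first residue as -1 (APE-4 = the 3rd residue before the A),
    positive offsets count C-terminal from the anchor's last residue
    (HRD+2 = 2 past the D, DFG+1 = 1 past the G).
    """

    kinase_id: str
    anchor: Anchor
    offset: int
    residue: str


def anchor_offset_residue(
    sequence: str,
    anchor: Anchor,
    offset: int,
    kinase_id: str = "",
    search_window: tuple[int, int] | None = None,
) -> AnchorResidueReport:
    """Extract the residue at ``anchor ± offset`` from a kinase-domain sequence.

    ``search_window`` (0-based half-open slice) disambiguates when the
    anchor tripeptide occurs more than once.
    """
    if anchor not in ("HRD", "APE", "DFG"):
        raise ParameterError(f"anchor must be HRD, APE or DFG, got {anchor!r}")
    if offset == 0:
        raise ParameterError("offset 0 is the anchor itself; use a nonzero offset")
    region = sequence
    region_start = 0
    if search_window is not None:
        region_start, end = search_window
        region = sequence[region_start:end]
    starts = []
    at = region.find(anchor)
    while at != -1:
        starts.append(region_start + at)
        at = region.find(anchor, at + 1)
    if not starts:
        raise AnchorNotFoundError(f"anchor {anchor} not found in sequence {kinase_id!r}")
    if len(starts) > 1:
        raise AnchorAmbiguityError(
            f"anchor {anchor} occurs {len(starts)} times in {kinase_id!r} at "
            f"{starts}; provide a search_window"
        )
    start = starts[0]
    # Negative offsets count N-terminal with the anchor's first residue as -1
    # (APE-4 of ...TIYAPE... is the T); positive offsets count C-terminal from
    # the anchor's last residue (HRD+2 is two past the D).
    idx = start + 1 + offset if offset < 0 else start + len(anchor) - 1 + offset
    if not 0 <= idx < len(sequence):
        raise ParameterError(
            f"{anchor}{offset:+d} falls outside the sequence (index {idx} of {len(sequence)})"
        )
    return AnchorResidueReport(
        kinase_id=kinase_id, anchor=anchor, offset=offset, residue=sequence[idx]
    )


def anchor_frequency(reports: Sequence[AnchorResidueReport]) -> dict[str, float]:
    """Fraction of each residue among anchor-offset reports (sums to 1)."""
    if not reports:
        raise InputError("no anchor reports supplied")
    counts = Counter(r.residue for r in reports)
    total = sum(counts.values())
    return {res: n / total for res, n in sorted(counts.items())}
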