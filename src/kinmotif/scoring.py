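"""Scansite-style PSSM scoring of candidate phosphosites.

A position-specific scoring matrix (PSSM) built from the capped linear
motif matrix assigns every candidate site window a lower-is-better match
score: the mean, over scored flank positions, of the log2 deviation of the
window residue's matrix value from the position's optimum.  A score of 0
means the window carries the column-optimal residue at every scored
position.  Because the score depends only on within-position ratios, it is
invariant to any per-position positive rescaling of the matrix, and
percentile-based target selection is invariant to any strictly monotone
transform of the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import ACCEPTORS, AMINO_ACIDS, PAD, PHOSPHO_RESIDUES, POSITIONS, WINDOW_LENGTH, window_index
from .errors import AlphabetError, InputError, ParameterError
from .opls import DEFAULT_LOG2_FLOOR, MotifMatrix

#: window characters marking a phosphorylated residue (uses the pT/pY columns)
MODIFIED_CODES = {"t": "pT", "y": "pY"}


@dataclass
class ScoringMatrix:
    """PSSM over the 20 amino acids at the 9 flank positions.

    ``entries`` holds strictly positive linear preference values (capped
    motif values, floored for positivity); ``modified_entries`` carries the
    phospho-Thr/phospho-Tyr columns, consulted only when a window marks a
    residue as phosphorylated (lowercase ``t``/``y``).  ``acceptor_set`` is
    the set of phospho-acceptor residues the kinase can use; sites with
    other acceptors are filtered, not scored.
    """

    kinase_id: str
    entries: pd.DataFrame  # positions x 20 AA, all > 0
    modified_entries: pd.DataFrame | None = None  # positions x (pT, pY)
    acceptor_set: frozenset[str] = frozenset({"S", "T"})
    neutral_value: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.entries = self.entries.reindex(
            index=pd.Index(POSITIONS, name="position"), columns=list(AMINO_ACIDS)
        ).astype(float)
        if self.entries.isna().any().any():
            self.entries = self.entries.fillna(self.neutral_value)
        if (self.entries <= 0).any().any():
            raise ParameterError("scoring matrix entries must be strictly positive")
        self.acceptor_set = frozenset(self.acceptor_set)
        if not self.acceptor_set <= set(ACCEPTORS):
            raise ParameterError(f"acceptor_set must be a subset of {ACCEPTORS}")

    def column_max(self) -> pd.Series:
        return self.entries.max(axis=1)

    def optimal_window(self) -> str:
        """The 9-mer taking the argmax residue at every position (score 0)."""
        return "".join(self.entries.loc[pos].idxmax() for pos in POSITIONS)


@dataclass(frozen=True)
class CandidateSite:
    """A phosphosite: acceptor residue plus its -5..+4 flanking window.

    ``window`` is exactly 9 characters (5 N-terminal, 4 C-terminal flank
    residues, acceptor excluded), padded with ``_`` past protein termini.
    Lowercase ``t``/``y`` mark phosphorylated flank residues.
    """

    protein_id: str
    site_position: int  # 1-based in the protein
    acceptor_residue: str
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise InputError(
                f"window must be {WINDOW_LENGTH} characters, got {len(self.window)!r} "
                f"for {self.protein_id}:{self.site_position}"
            )
        if self.acceptor_residue not in ACCEPTORS:
            raise InputError(
                f"acceptor must be one of {ACCEPTORS}, got {self.acceptor_residue!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.site_position)


@dataclass(frozen=True)
class SiteScore:
    """Lower-is-better motif-match score; 0 = perfect match at every position."""

    protein_id: str
    site_position: int
    kinase_id: str
    score: float
    percentile_rank: float | None = None  # fraction of scored sites with score <= this

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.site_position)


def build_scoring_matrix(
    motif: MotifMatrix,
    acceptor_set: Iterable[str] = ("S", "T"),
    floor: float = DEFAULT_LOG2_FLOOR,
) -> ScoringMatrix:
    """Derive a PSSM from a capped linear motif matrix.

    The 20 amino-acid columns become the scoring entries, clamped below at
    ``floor`` to preserve positivity; missing cells (residues the library
    carried no information for) get the neutral value 1.  The pT/pY columns
    move to the modified-residue table.
    """
    motif.require_stage("capped")
    entries = motif.values[list(AMINO_ACIDS)].clip(lower=floor).fillna(1.0)
    modified = motif.values[list(PHOSPHO_RESIDUES)].clip(lower=floor)
    return ScoringMatrix(
        kinase_id=motif.kinase_id,
        entries=entries,
        modified_entries=modified,
        acceptor_set=frozenset(acceptor_set),
        provenance=f"capped motif, n_replicates={motif.n_replicates}, floor={floor!r}",
    )


def score_site(matrix: ScoringMatrix, site: CandidateSite) -> SiteScore:
    """Score one site window against the PSSM.

    score = mean over non-padding positions of
    ``log2(max(column)) - log2(entry(position, residue))`` — nonnegative,
    0 iff the window is column-optimal everywhere.  Padding ``_`` positions
    are excluded from the mean, keeping truncated windows comparable.
    """
    col_max = matrix.column_max()
    total = 0.0
    n = 0
    for pos in POSITIONS:
        ch = site.window[window_index(pos)]
        if ch == PAD:
            continue
        if ch in MODIFIED_CODES:
            code = MODIFIED_CODES[ch]
            if matrix.modified_entries is not None and pd.notna(
                matrix.modified_entries.at[pos, code]
            ):
                value = float(matrix.modified_entries.at[pos, code])
            else:
                value = matrix.neutral_value
        elif ch in AMINO_ACIDS:
            value = float(matrix.entries.at[pos, ch])
        else:
            raise AlphabetError(
                f"window {site.window!r} of {site.protein_id}:{site.site_position} "
                f"contains unknown character {ch!r} at position {pos:+d}"
            )
        # A modified or neutral value may exceed the plain-AA column max;
        # never let a single position contribute a negative deviation.
        total += max(0.0, math.log2(float(col_max.at[pos])) - math.log2(value))
        n += 1
    if n == 0:
        raise InputError(f"window of {site.protein_id}:{site.site_position} is all padding")
    return SiteScore(
        protein_id=site.protein_id,
        site_position=site.site_position,
        kinase_id=matrix.kinase_id,
        score=total / n,
    )


def score_sites(matrix: ScoringMatrix, sites: Sequence[CandidateSite]) -> list[SiteScore]:
    """Score many sites and attach percentile ranks (fraction scoring <= each)."""
    raw = [score_site(matrix, s) for s in sites]
    values = np.array([s.score for s in raw])
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    # percentile rank with ties sharing the max rank of their tie group
    sorted_vals = values[order]
    ranks_sorted = np.searchsorted(sorted_vals, sorted_vals, side="right") / len(values)
    ranks[order] = ranks_sorted
    return [
        SiteScore(s.protein_id, s.site_position, s.kinase_id, s.score, float(r))
        for s, r in zip(raw, ranks)
    ]


def filter_sites(
    sites: Sequence[CandidateSite],
    matrix: ScoringMatrix,
    dedupe: bool = True,
    class_labels: Mapping[tuple[str, int], str] | None = None,
) -> list[CandidateSite]:
    """Remove sites the kinase cannot phosphorylate; optionally deduplicate.

    Drops sites whose acceptor residue is outside the matrix's acceptor
    set.  With ``dedupe``, repeated (protein_id, site_position) keys keep
    the first occurrence.  ``class_labels``, when given, keeps only sites
    labelled ``"1"`` (high-confidence localization).
    """
    seen: set[tuple[str, int]] = set()
    out = []
    for site in sites:
        if site.acceptor_residue not in matrix.acceptor_set:
            continue
        if class_labels is not None and class_labels.get(site.key) != "1":
            continue
        if dedupe:
            if site.key in seen:
                continue
            seen.add(site.key)
        out.append(site)
    return out


def percentile_select(
    scores: Sequence[SiteScore], fraction: float
) -> list[SiteScore]:
    """Select the best-scoring fraction of sites (lowest scores).

    Takes the ``ceil(fraction * n)`` lowest scores; ties with the boundary
    score are all included, so the selection can exceed that count.  Output
    is ordered by (score, protein_id, site_position) for determinism.
    """
    if not scores:
        raise ParameterError("no scores to select from")
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    ordered = sorted(scores, key=lambda s: (s.score, s.protein_id, s.site_position))
    k = math.ceil(fraction * len(ordered))
    cutoff = ordered[k - 1].score
    return [s for s in ordered if s.score <= cutoff]


def overlap_analysis(
    selected: Mapping[str, set], reference: str | None = None
) -> dict:
    """Exact Venn region counts over the nonempty membership patterns.

    ``selected`` maps kinase id -> set of site keys (2-6 sets).  Returns
    ``regions`` keyed by the sorted tuple of member kinases joined with
    ``&``, plus, when ``reference`` names a kinase, the fraction of its
    sites shared with at least one other set.
    """
    k = len(selected)
    if not 2 <= k <= 6:
        raise ParameterError(f"overlap analysis supports 2-6 sets, got {k}")
    names = sorted(selected)
    universe = set().union(*selected.values())
    regions: dict[str, int] = {}
    for element in universe:
        members = tuple(n for n in names if element in selected[n])
        key = "&".join(members)
        regions[key] = regions.get(key, 0) + 1
    result: dict = {"regions": regions, "total": len(universe)}
    if reference is not None:
        if reference not in selected:
            raise InputError(f"reference kinase {reference!r} not among the sets")
        ref = selected[reference]
        others = set().union(*(v for n, v in selected.items() if n != reference))
        result["reference"] = reference
        result["reference_shared_fraction"] = (
            len(ref & others) / len(ref) if ref else float("nan")
        )
    return result


def score_correlation(
    scores_a: Sequence[SiteScore], scores_b: Sequence[SiteScore]
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between two kinases' scores over the same sites."""
    a = {s.key: s.score for s in scores_a}
    b = {s.key: s.score for s in scores_b}
    if set(a) != set(b):
        diff = set(a) ^ set(b)
        raise InputError(f"score lists cover different sites; {len(diff)} mismatched keys")
    keys = sorted(a)
    table = pd.DataFrame(
        {
            "protein_id": [k[0] for k in keys],
            "site_position": [k[1] for k in keys],
            "score_a": [a[k] for k in keys],
            "score_b": [b[k] for k in keys],
        }
    )
    va, vb = table["score_a"].to_numpy(), table["score_b"].to_numpy()
    if va.std() == 0 or vb.std() == 0:
        raise InputError("zero-variance score list; correlation undefined")
    r = float(np.corrcoef(va, vb)[0, 1])
    return r, table
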