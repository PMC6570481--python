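"""Normalization of oriented-peptide-library (OPLS) spot intensities.

The raw readout of an OPLS experiment is a grid of spot intensities, one
spot per peptide pool, where each pool fixes one residue at one flanking
position relative to the phospho-acceptor.  The processing pipeline is:

1. **normalize** each replicate: divide every spot by the mean intensity of
   all fixed residues at that position, so each position's profile has mean
   1 and a global exposure factor cancels;
2. **average** normalized replicates element-wise;
3. **cap** acceptor-like fixed residues (Ser/Thr in the Ser/Thr library,
   Tyr in the Tyr library) at 1 when they exceed 1 — such pools present a
   second acceptor site, so high intensity there overreports preference;
4. **log2-transform** for display (heatmaps, sequence logos), with a small
   positive floor so zero spots stay finite.

Clustering and substrate scoring consume the *linear capped* matrix; logos
consume the *log2* matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .alphabet import ACCEPTORS, GRID_RESIDUES, POSITIONS
from .errors import DegenerateDataError, InputError, ParameterError, StageError

Library = Literal["ST", "Y"]
Stage = Literal["raw", "normalized", "averaged", "capped", "log2"]

#: Default floor applied before log2 so zero/near-zero spots stay finite.
DEFAULT_LOG2_FLOOR = 2.0 ** -6


def _empty_flank() -> pd.DataFrame:
    return pd.DataFrame(
        np.nan, index=pd.Index(POSITIONS, name="position"), columns=list(GRID_RESIDUES)
    )


def _coerce_flank(values: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically order a flank table (positions x residues)."""
    extra_rows = set(values.index) - set(POSITIONS)
    extra_cols = set(values.columns) - set(GRID_RESIDUES)
    if extra_rows or extra_cols:
        raise InputError(
            f"unexpected flank labels: positions {sorted(extra_rows)}, residues {sorted(extra_cols)}"
        )
    out = _empty_flank()
    out.loc[values.index, values.columns] = values.astype(float)
    return out


@dataclass
class SpotGrid:
    """One replicate's raw OPLS intensities.

    ``flank`` is a 9 x 22 table (rows: positions -5..+4 excluding 0;
    columns: 20 amino acids + pT + pY) of nonnegative spot intensities;
    NaN marks a failed/missing spot.  ``acceptor`` optionally holds the
    three fully degenerate acceptor-pool intensities keyed S/T/Y.
    """

    kinase_id: str
    library: Library
    replicate_id: str
    flank: pd.DataFrame
    acceptor: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.library not in ("ST", "Y"):
            raise ParameterError(f"library must be 'ST' or 'Y', got {self.library!r}")
        self.flank = _coerce_flank(self.flank)
        if (self.flank < 0).any().any():
            raise InputError("spot intensities must be nonnegative")
        if self.acceptor is not None:
            extra = set(self.acceptor.index) - set(ACCEPTORS)
            if extra:
                raise InputError(f"unknown acceptor pools: {sorted(extra)}")
            self.acceptor = self.acceptor.astype(float).reindex(list(ACCEPTORS))

    @property
    def n_missing(self) -> int:
        return int(self.flank.isna().sum().sum())


@dataclass
class MotifMatrix:
    """A kinase's phosphorylation-site motif at a given processing stage.

    Same index layout as :class:`SpotGrid.flank`.  ``acceptor_pref`` holds
    mean-normalized acceptor-pool values (mean 1 over present pools) when
    the degenerate pools were measured.  ``capped_cells`` records which
    (position, residue) cells the capping step actually modified.
    """

    kinase_id: str
    library: Library
    stage: Stage
    values: pd.DataFrame
    acceptor_pref: pd.Series | None = None
    n_replicates: int = 1
    floor: float | None = None
    capped_cells: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _coerce_flank(self.values)
        if self.acceptor_pref is not None:
            self.acceptor_pref = self.acceptor_pref.astype(float).reindex(list(ACCEPTORS))

    def require_stage(self, *stages: Stage) -> None:
        if self.stage not in stages:
            raise StageError(
                f"expected a motif at stage {' or '.join(stages)}, got {self.stage!r}"
            )

    @property
    def completeness(self) -> float:
        """Fraction of the 198 flank cells that are present (non-NaN)."""
        return float(1.0 - self.values.isna().to_numpy().mean())


def normalize_spot_grid(grid: SpotGrid) -> MotifMatrix:
    """Divide every spot by the mean intensity of its position.

    The mean at each position is taken over the fixed residues present at
    that position (all 22 when the grid is complete), so each position's
    normalized profile has mean exactly 1 and any per-blot global exposure
    factor cancels.
    """
    raw = grid.flank
    means = raw.mean(axis=1, skipna=True)  # per-position mean over residues
    bad = means.index[(means == 0) | means.isna()]
    if len(bad):
        raise DegenerateDataError(
            f"all-zero or all-missing intensity column(s) at position(s) {list(bad)} "
            f"for kinase {grid.kinase_id!r} replicate {grid.replicate_id!r}"
        )
    values = raw.div(means, axis=0)
    acceptor = None
    if grid.acceptor is not None:
        acceptor = _normalize_acceptor_pools(grid.acceptor)
    return MotifMatrix(
        kinase_id=grid.kinase_id,
        library=grid.library,
        stage="normalized",
        values=values,
        acceptor_pref=acceptor,
        n_replicates=1,
    )


def _normalize_acceptor_pools(pools: pd.Series) -> pd.Series:
    present = pools.dropna()
    if len(present) < 2:
        raise InputError("acceptor preference needs at least 2 of the 3 degenerate pools")
    mean = present.mean()
    if mean == 0:
        raise DegenerateDataError("all acceptor pools have zero intensity")
    return pools / mean


def average_replicates(motifs: Sequence[MotifMatrix]) -> MotifMatrix:
    """Element-wise arithmetic mean of normalized replicate matrices."""
    if not motifs:
        raise InputError("no replicate matrices supplied")
    first = motifs[0]
    for m in motifs:
        m.require_stage("normalized")
        if (m.kinase_id, m.library) != (first.kinase_id, first.library):
            raise InputError(
                f"replicates disagree: {m.kinase_id}/{m.library} vs "
                f"{first.kinase_id}/{first.library}"
            )
    if len(motifs) < 2:
        warnings.warn(
            f"averaging a single replicate for {first.kinase_id}; the protocol "
            "calls for n >= 2",
            stacklevel=2,
        )
    stacked = np.stack([m.values.to_numpy() for m in motifs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(stacked, axis=0)
    values = pd.DataFrame(mean, index=first.values.index, columns=first.values.columns)
    acc = None
    accs = [m.acceptor_pref for m in motifs if m.acceptor_pref is not None]
    if accs:
        acc = pd.concat(accs, axis=1).mean(axis=1, skipna=True)
    return MotifMatrix(
        kinase_id=first.kinase_id,
        library=first.library,
        stage="averaged",
        values=values,
        acceptor_pref=acc,
        n_replicates=len(motifs),
    )


def cappable_residues(library: Library) -> tuple[str, ...]:
    """Fixed residues that present a second acceptor site in a given library."""
    return ("S", "T") if library == "ST" else ("Y",)


def cap_acceptor_like_residues(
    motif: MotifMatrix,
    exceptions: Iterable[tuple[int, str]] = (),
) -> MotifMatrix:
    """Cap acceptor-like fixed residues at 1 where their value exceeds 1.

    A fixed Ser/Thr (Ser/Thr library) or fixed Tyr (Tyr library) pool
    carries a second phospho-acceptor besides the central one, so values
    above 1 there need not reflect true flank preference.  Cells listed in
    ``exceptions`` are left untouched (e.g. a +1 Tyr judged to be a real
    aromatic preference).  Idempotent.
    """
    motif.require_stage("averaged", "capped")
    targets = cappable_residues(motif.library)
    exceptions = list(exceptions)
    for pos, res in exceptions:
        if res not in targets or pos not in POSITIONS:
            warnings.warn(
                f"cap exception ({pos}, {res}) names a cell that is never capped "
                f"in the {motif.library} library; ignored",
                stacklevel=2,
            )
    values = motif.values.copy()
    modified: list[tuple[int, str]] = []
    for res in targets:
        for pos in POSITIONS:
            if (pos, res) in exceptions:
                continue
            v = values.at[pos, res]
            if pd.notna(v) and v > 1.0:
                values.at[pos, res] = 1.0
                modified.append((pos, res))
    return replace(
        motif, stage="capped", values=values, capped_cells=sorted(set(motif.capped_cells) | set(modified))
    )


def log_transform(motif: MotifMatrix, floor: float = DEFAULT_LOG2_FLOOR) -> MotifMatrix:
    """log2 of the capped matrix, flooring values below ``floor`` first."""
    if not floor > 0:
        raise ParameterError(f"floor must be positive, got {floor}")
    motif.require_stage("capped")
    values = np.log2(motif.values.clip(lower=floor))
    return replace(motif, stage="log2", values=values, floor=floor)


def acceptor_preference(obj: SpotGrid | MotifMatrix) -> pd.DataFrame:
    """Normalized values and fractions for the S/T/Y degenerate acceptor pools.

    Returns a table with one row per present pool and columns
    ``normalized`` (pool / mean of present pools, mirroring the flank
    normalization) and ``fraction`` (pools rescaled to sum to 1).
    """
    if isinstance(obj, SpotGrid):
        if obj.acceptor is None:
            raise InputError("grid carries no acceptor pools")
        normalized = _normalize_acceptor_pools(obj.acceptor)
    else:
        if obj.acceptor_pref is None:
            raise InputError("motif carries no acceptor pools")
        normalized = _normalize_acceptor_pools(obj.acceptor_pref)
    present = normalized.dropna()
    return pd.DataFrame(
        {"normalized": present, "fraction": present / present.sum()}
    ).rename_axis("acceptor")


def run_motif_pipeline(
    grids: Sequence[SpotGrid],
    cap_exceptions: Iterable[tuple[int, str]] = (),
    floor: float = DEFAULT_LOG2_FLOOR,
) -> tuple[MotifMatrix, MotifMatrix]:
    """Full pipeline: normalize each replicate, average, cap, then log2.

    Returns ``(capped, log2)`` matrices — the linear capped matrix feeds
    clustering and PSSM scoring; the log2 matrix feeds heatmaps and logos.
    """
    if not grids:
        raise InputError("no spot grids supplied")
    normalized = [normalize_spot_grid(g) for g in grids]
    averaged = average_replicates(normalized)
    capped = cap_acceptor_like_residues(averaged, cap_exceptions)
    logged = log_transform(capped, floor=floor)
    return capped, logged
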