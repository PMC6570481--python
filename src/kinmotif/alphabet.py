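"""Residue alphabets and position conventions shared across the package.

An oriented peptide library fixes one residue (``Z``) at one flanking
position relative to a central phospho-acceptor.  Flank positions are
numbered -5..-1, +1..+4 (nine positions; there is no 0 column because the
acceptor itself is profiled by three separate fully degenerate pools).  The
fixed residue may be any of the 20 standard amino acids or phospho-Thr
(``pT``) / phospho-Tyr (``pY``), giving a 9 x 22 = 198-pool grid.
"""

from __future__ import annotations

# Flank positions relative to the phospho-acceptor (no 0 column).
POSITIONS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4)

# 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# Phospho-residues available as fixed residues in the library.
PHOSPHO_RESIDUES: tuple[str, ...] = ("pT", "pY")

# Full fixed-residue alphabet of the oriented library grid (22 codes).
GRID_RESIDUES: tuple[str, ...] = AMINO_ACIDS + PHOSPHO_RESIDUES

# Phospho-acceptor identities of the three fully degenerate pools.
ACCEPTORS: tuple[str, ...] = ("S", "T", "Y")

# Padding character used in site windows that run past a protein terminus.
PAD = "_"

N_POSITIONS = len(POSITIONS)
N_GRID_RESIDUES = len(GRID_RESIDUES)
N_POOLS = N_POSITIONS * N_GRID_RESIDUES  # 198

# Window layout for candidate sites: 5 N-terminal + 4 C-terminal residues.
WINDOW_LENGTH = 9


def window_index(position: int) -> int:
    """Map a flank position to its 0-based index in a 9-mer window string."""
    if position not in POSITIONS:
        raise ValueError(f"invalid flank position {position!r}; expected one of {POSITIONS}")
    return position + 5 if position < 0 else position + 4
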