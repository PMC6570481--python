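"""Plain-text file dialects for every object in the pipeline.

All tabular formats are TSV/CSV with ``#``-prefixed metadata headers; all
floats are written at 6 significant digits, which makes read-then-write a
byte-identical round trip.  FASTA and Newick go through Biopython.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO

from .alphabet import ACCEPTORS, AMINO_ACIDS, GRID_RESIDUES, PHOSPHO_RESIDUES, POSITIONS
from .errors import ParseError
from .kinetics import TimeCourse
from .opls import MotifMatrix, SpotGrid
from .scoring import CandidateSite, ScoringMatrix, SiteScore

try:
    _VERSION = version("kinmotif")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"

_FMT = "%.6g"


def _fmt(x: float) -> str:
    return "NA" if pd.isna(x) else _FMT % x


def _parse_float(tok: str, line: int, path: str) -> float:
    if tok == "NA":
        return float("nan")
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"not a number: {tok!r}", line=line, path=path) from None


def _grid_lines(values: pd.DataFrame, residues: Sequence[str]) -> list[str]:
    lines = ["position\t" + "\t".join(residues)]
    for pos in POSITIONS:
        row = [str(pos)] + [_fmt(values.at[pos, r]) for r in residues]
        lines.append("\t".join(row))
    return lines


def _read_header(lines: list[str]) -> tuple[dict[str, str], int]:
    """Parse leading '# key=value' lines; returns (metadata, first data line index)."""
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i].lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
        i += 1
    return meta, i


def _read_grid_block(
    lines: list[str], start: int, path: str
) -> tuple[pd.DataFrame, int]:
    header = lines[start].rstrip("\n").split("\t")
    if header[0] != "position":
        raise ParseError(f"expected 'position' header, got {header[0]!r}", line=start + 1, path=path)
    residues = header[1:]
    unknown = set(residues) - set(GRID_RESIDUES)
    if unknown:
        raise ParseError(f"unknown residue codes {sorted(unknown)}", line=start + 1, path=path)
    values = pd.DataFrame(np.nan, index=pd.Index(POSITIONS, name="position"), columns=residues)
    i = start + 1
    for _ in POSITIONS:
        if i >= len(lines):
            raise ParseError("truncated grid block", line=i + 1, path=path)
        toks = lines[i].rstrip("\n").split("\t")
        if len(toks) != len(residues) + 1:
            raise ParseError(
                f"expected {len(residues) + 1} fields, got {len(toks)}", line=i + 1, path=path
            )
        try:
            pos = int(toks[0])
        except ValueError:
            raise ParseError(f"bad position label {toks[0]!r}", line=i + 1, path=path) from None
        if pos not in POSITIONS:
            raise ParseError(f"position {pos} outside -5..+4 (no 0)", line=i + 1, path=path)
        for res, tok in zip(residues, toks[1:]):
            values.at[pos, res] = _parse_float(tok, i + 1, path)
        i += 1
    return values, i


def _read_acceptor_block(
    lines: list[str], start: int, path: str
) -> tuple[pd.Series | None, int]:
    i = start
    if i < len(lines) and lines[i].strip() == "# acceptor":
        i += 1
        pools: dict[str, float] = {}
        while i < len(lines) and lines[i].strip():
            toks = lines[i].rstrip("\n").split("\t")
            if len(toks) != 2 or toks[0] not in ACCEPTORS:
                raise ParseError(f"bad acceptor line {lines[i]!r}", line=i + 1, path=path)
            pools[toks[0]] = _parse_float(toks[1], i + 1, path)
            i += 1
        return pd.Series(pools).reindex(list(ACCEPTORS)), i
    return None, i


def _acceptor_lines(pools: pd.Series | None) -> list[str]:
    if pools is None:
        return []
    lines = ["# acceptor"]
    for a in ACCEPTORS:
        v = pools.get(a, np.nan)
        if pd.notna(v):
            lines.append(f"{a}\t{_fmt(v)}")
    return lines


# ---------------------------------------------------------------------------
# SpotGrid


def write_spot_grid(grid: SpotGrid, path: str | Path) -> None:
    lines = [
        f"# kinmotif={_VERSION} format=spotgrid",
        f"# kinase={grid.kinase_id}",
        f"# library={grid.library}",
        f"# replicate={grid.replicate_id}",
    ]
    lines += _grid_lines(grid.flank, list(GRID_RESIDUES))
    lines += _acceptor_lines(grid.acceptor)
    Path(path).write_text("\n".join(lines) + "\n")


def read_spot_grid(path: str | Path) -> SpotGrid:
    p = str(path)
    lines = Path(path).read_text().splitlines()
    meta, i = _read_header(lines)
    for key in ("kinase", "library", "replicate"):
        if key not in meta:
            raise ParseError(f"missing '# {key}=' header", path=p)
    values, i = _read_grid_block(lines, i, p)
    acceptor, i = _read_acceptor_block(lines, i, p)
    return SpotGrid(
        kinase_id=meta["kinase"],
        library=meta["library"],  # type: ignore[arg-type]
        replicate_id=meta["replicate"],
        flank=values,
        acceptor=acceptor,
    )


# ---------------------------------------------------------------------------
# MotifMatrix


def write_motif_matrix(motif: MotifMatrix, path: str | Path) -> None:
    lines = [
        f"# kinmotif={_VERSION} format=motif",
        f"# kinase={motif.kinase_id}",
        f"# library={motif.library}",
        f"# stage={motif.stage}",
        f"# n_replicates={motif.n_replicates}",
    ]
    if motif.floor is not None:
        lines.append(f"# floor={_FMT % motif.floor}")
    if motif.capped_cells:
        cells = ";".join(f"{pos},{res}" for pos, res in motif.capped_cells)
        lines.append(f"# capped_cells={cells}")
    lines += _grid_lines(motif.values, list(GRID_RESIDUES))
    lines += _acceptor_lines(motif.acceptor_pref)
    Path(path).write_text("\n".join(lines) + "\n")


def read_motif_matrix(path: str | Path) -> MotifMatrix:
    p = str(path)
    lines = Path(path).read_text().splitlines()
    meta, i = _read_header(lines)
    for key in ("kinase", "library", "stage"):
        if key not in meta:
            raise ParseError(f"missing '# {key}=' header", path=p)
    values, i = _read_grid_block(lines, i, p)
    acceptor, i = _read_acceptor_block(lines, i, p)
    capped = []
    if meta.get("capped_cells"):
        for item in meta["capped_cells"].split(";"):
            pos, res = item.split(",")
            capped.append((int(pos), res))
    return MotifMatrix(
        kinase_id=meta["kinase"],
        library=meta["library"],  # type: ignore[arg-type]
        stage=meta["stage"],  # type: ignore[arg-type]
        values=values,
        acceptor_pref=acceptor,
        n_replicates=int(meta.get("n_replicates", 1)),
        floor=float(meta["floor"]) if "floor" in meta else None,
        capped_cells=capped,
    )


# ---------------------------------------------------------------------------
# ScoringMatrix


def write_scoring_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    residues = list(AMINO_ACIDS)
    table = matrix.entries.copy()
    if matrix.modified_entries is not None:
        residues += list(PHOSPHO_RESIDUES)
        table = pd.concat([table, matrix.modified_entries], axis=1)
    lines = [
        f"# kinmotif={_VERSION} format=pssm",
        f"# kinase={matrix.kinase_id}",
        f"# acceptor_set={''.join(sorted(matrix.acceptor_set))}",
        f"# neutral={_FMT % matrix.neutral_value}",
        f"# provenance={matrix.provenance}",
    ]
    lines += _grid_lines(table, residues)
    Path(path).write_text("\n".join(lines) + "\n")


def read_scoring_matrix(path: str | Path) -> ScoringMatrix:
    p = str(path)
    lines = Path(path).read_text().splitlines()
    meta, i = _read_header(lines)
    if "kinase" not in meta:
        raise ParseError("missing '# kinase=' header", path=p)
    values, i = _read_grid_block(lines, i, p)
    modified = None
    if set(PHOSPHO_RESIDUES) <= set(values.columns):
        modified = values[list(PHOSPHO_RESIDUES)]
    return ScoringMatrix(
        kinase_id=meta["kinase"],
        entries=values[list(AMINO_ACIDS)],
        modified_entries=modified,
        acceptor_set=frozenset(meta.get("acceptor_set", "ST")),
        neutral_value=float(meta.get("neutral", 1.0)),
        provenance=meta.get("provenance", ""),
    )


# ---------------------------------------------------------------------------
# candidate sites


def write_sites_tsv(sites: Sequence[CandidateSite], path: str | Path) -> None:
    lines = ["protein_id\tposition\tacceptor\twindow"]
    for s in sites:
        lines.append(f"{s.protein_id}\t{s.site_position}\t{s.acceptor_residue}\t{s.window}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sites_tsv(path: str | Path) -> list[CandidateSite]:
    p = str(path)
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:4] != ["protein_id", "position", "acceptor", "window"]:
        raise ParseError("missing site TSV header", line=1, path=p)
    sites = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split("\t")
        if len(toks) < 4:
            raise ParseError(f"expected 4 fields, got {len(toks)}", line=i, path=p)
        try:
            pos = int(toks[1])
        except ValueError:
            raise ParseError(f"bad site position {toks[1]!r}", line=i, path=p) from None
        sites.append(CandidateSite(toks[0], pos, toks[2], toks[3]))
    return sites


def write_sites_fasta(sites: Sequence[CandidateSite], path: str | Path) -> None:
    """FASTA of 10-mers (5 flank + acceptor + 4 flank), headers ``>protein|pos|acceptor``."""
    with open(path, "w") as fh:
        for s in sites:
            seq = s.window[:5] + s.acceptor_residue + s.window[5:]
            fh.write(f">{s.protein_id}|{s.site_position}|{s.acceptor_residue}\n{seq}\n")


def read_sites_fasta(path: str | Path) -> list[CandidateSite]:
    sites = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise ParseError(
                f"site FASTA header must be 'protein|pos|acceptor', got {record.id!r}",
                path=str(path),
            )
        protein, pos, acceptor = parts
        seq = str(record.seq)
        if len(seq) != 10:
            raise ParseError(
                f"site record {record.id!r} must be a 10-mer, got {len(seq)}", path=str(path)
            )
        sites.append(CandidateSite(protein, int(pos), acceptor, seq[:5] + seq[6:]))
    return sites


def read_phosphositeplus_dump(path: str | Path) -> list[CandidateSite]:
    """Reader for PhosphoSitePlus-style flat dumps (tab-delimited).

    Expects columns ``ACC_ID`` (or ``PROTEIN``), ``MOD_RSD`` (e.g. ``S25-p``)
    and ``SITE_+/-7_AA``; the +/-7 window is trimmed to -5..+4 and padded
    with ``_``.  Provided for convenience; nothing in the package requires it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    id_col = "ACC_ID" if "ACC_ID" in df.columns else "PROTEIN"
    needed = {id_col, "MOD_RSD", "SITE_+/-7_AA"}
    if not needed <= set(df.columns):
        raise ParseError(f"dump lacks columns {sorted(needed - set(df.columns))}", path=str(path))
    sites = []
    for _, row in df.iterrows():
        mod = str(row["MOD_RSD"])
        acceptor = mod[0]
        pos = int(mod[1:].split("-")[0])
        w15 = str(row["SITE_+/-7_AA"]).upper().replace("_", "_")
        # center is index 7 in a +/-7 window
        flank = (w15[2:7] + w15[8:12]).replace("X", "_")
        sites.append(CandidateSite(str(row[id_col]), pos, acceptor, flank))
    return sites


def write_scores_tsv(scores: Sequence[SiteScore], path: str | Path) -> None:
    lines = ["protein_id\tposition\tkinase\tscore\tpercentile"]
    for s in scores:
        pct = "NA" if s.percentile_rank is None else _FMT % s.percentile_rank
        lines.append(
            f"{s.protein_id}\t{s.site_position}\t{s.kinase_id}\t{_FMT % s.score}\t{pct}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequences, trees, time courses, reports


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain or aligned FASTA as an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file into a Bio.Phylo tree."""
    return Phylo.read(str(path), "newick")


def parse_newick(newick: str):
    return Phylo.read(StringIO(newick), "newick")


def write_timecourses(courses: Sequence[TimeCourse], path: str | Path) -> None:
    rows = []
    for tc in courses:
        for t, c in zip(tc.times, tc.counts):
            rows.append({"label": tc.label, "replicate": tc.replicate_id, "time_min": t, "cpm": c})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FMT)


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    df = pd.read_csv(path)
    needed = {"label", "replicate", "time_min", "cpm"}
    if not needed <= set(df.columns):
        raise ParseError(f"missing columns {sorted(needed - set(df.columns))}", path=str(path))
    courses = []
    for (label, rep), group in df.groupby(["label", "replicate"], sort=True):
        courses.append(
            TimeCourse(
                label=str(label),
                replicate_id=str(rep),
                times=group["time_min"].to_numpy(),
                counts=group["cpm"].to_numpy(),
            )
        )
    return courses


def write_similarity_tsv(sim, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kinmotif={_VERSION} format=similarity metric={sim.metric_tag}\n")
        sim.values.to_csv(fh, sep="\t", float_format=_FMT, index_label="kinase")


def write_json_report(obj: Mapping, path: str | Path) -> None:
    payload = {"kinmotif": _VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
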