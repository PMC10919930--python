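"""Alignment and trait-table I/O, and gap-aware column <-> genome coordinate maps.

The multiple sequence alignment is held as a species-by-column character
matrix (:class:`AlignmentMatrix`).  Columns are 1-based throughout, matching
the convention of site tables in comparative-genomics reports.  Genomic
coordinates are 1-based inclusive internally; BED output converts to 0-based
half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .errors import CoordinateRangeError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical unambiguous bases
BASES = "ACGT"
#: gap character after normalization ('.' is normalized to '-')
GAP = "-"
#: characters kept verbatim in the matrix; anything else becomes 'N'
_KNOWN = set("ACGTN-RYSWKMBDHV")

HABITATS = ("aquatic", "terrestrial")


@dataclass
class AlignmentMatrix:
    """Species x column character matrix with unique row ids.

    ``chars`` is an (n_species, n_columns) array of single uppercase
    characters over {A,C,G,T,N,-, IUPAC ambiguity codes}.  Column indexing in
    the public API is 1-based.
    """

    ids: list[str]
    chars: np.ndarray

    def __post_init__(self) -> None:
        self.chars = np.asarray(self.chars, dtype="U1")
        if self.chars.ndim != 2:
            raise FormatError("alignment matrix must be 2-dimensional")
        if len(self.ids) != self.chars.shape[0]:
            raise FormatError(
                f"{len(self.ids)} ids for {self.chars.shape[0]} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({s for s in self.ids if self.ids.count(s) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        if self.chars.shape[1] < 1:
            raise FormatError("alignment has zero columns")

    @property
    def n_species(self) -> int:
        return self.chars.shape[0]

    @property
    def n_columns(self) -> int:
        return self.chars.shape[1]

    def row(self, species: str) -> np.ndarray:
        return self.chars[self.ids.index(species)]

    def column(self, col: int) -> np.ndarray:
        """Characters of 1-based column ``col`` in row order."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside [1, {self.n_columns}]")
        return self.chars[:, col - 1]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n")
                seq = "".join(self.chars[i])
                for j in range(0, len(seq), 60):
                    fh.write(seq[j : j + 60] + "\n")


def read_alignment(path: str | Path, format: str = "fasta") -> AlignmentMatrix:
    """Read an aligned FASTA or Clustal file into an :class:`AlignmentMatrix`.

    Characters are uppercased, ``.`` is normalized to ``-`` and anything
    outside the known alphabet is mapped to ``N`` (count logged).
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sequence ids")
    mat = np.array([list(str(rec.seq).upper()) for rec in aln], dtype="U1")
    mat[mat == "."] = GAP
    unknown = ~np.isin(mat, list(_KNOWN))
    n_unknown = int(unknown.sum())
    if n_unknown:
        logger.warning("%s: %d unknown characters mapped to N", path, n_unknown)
        mat[unknown] = "N"
    return AlignmentMatrix(ids=ids, chars=mat)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a species trait TSV (species, mass_kg, habitat[, clade]).

    Returns a DataFrame with a computed ``log_mass`` column (natural log of
    mass in kg).  Raises :class:`ValidationError` for non-positive masses,
    unknown habitats or duplicate species, naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    required = {"species", "mass_kg", "habitat"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValidationError(f"{path}: duplicate species {dup}")
    for _, row in df.iterrows():
        if pd.isna(row["mass_kg"]) or row["mass_kg"] <= 0:
            raise ValidationError(
                f"{path}: species {row['species']!r} has non-positive mass"
            )
        if pd.isna(row["habitat"]) or row["habitat"] not in HABITATS:
            raise ValidationError(
                f"{path}: species {row['species']!r} has habitat "
                f"{row['habitat']!r}, expected one of {HABITATS}"
            )
    df = df.copy()
    df["log_mass"] = np.log(df["mass_kg"].astype(float))
    if "clade" not in df.columns:
        df["clade"] = pd.NA
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("species", "mass_kg", "habitat", "clade") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


@dataclass
class ColumnMap:
    """Bijection between non-gap columns of a reference row and a genomic span.

    ``orientation='forward'`` means the first non-gap reference base sits at
    ``anchor`` and coordinates increase with column index;
    ``'reverse'`` means coordinates decrease (the reference row is the
    reverse-complement strand of the assembly).
    """

    ref_id: str
    anchor: int
    orientation: str
    # 1-based coordinate per column; 0 marks unmapped (reference-row gap)
    _col_coord: np.ndarray = field(repr=False)
    # column (1-based) per coordinate offset from span_start
    _coord_col: np.ndarray = field(repr=False)
    span_start: int = 0
    span_end: int = 0

    @property
    def n_columns(self) -> int:
        return len(self._col_coord)

    @property
    def n_mapped(self) -> int:
        return int((self._col_coord > 0).sum())

    def coord_of_column(self, col: int) -> int | None:
        """Genomic coordinate of 1-based ``col``; None if the reference row is
        gapped there ("unmapped")."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside [1, {self.n_columns}]")
        c = int(self._col_coord[col - 1])
        return c if c > 0 else None

    def column_of_coord(self, coord: int) -> int:
        """1-based alignment column holding genomic ``coord``."""
        if not self.span_start <= coord <= self.span_end:
            raise CoordinateRangeError(
                f"coordinate {coord} outside covered span "
                f"[{self.span_start}, {self.span_end}]"
            )
        return int(self._coord_col[coord - self.span_start])


def build_column_map(
    aln: AlignmentMatrix,
    ref_row: str,
    anchor: int,
    orientation: str = "forward",
) -> ColumnMap:
    """Build the gap-aware map between alignment columns and coordinates of
    the reference row's source genome.

    ``anchor`` is the 1-based genomic position of the reference row's first
    non-gap base.  Reference-row gap columns are unmapped.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    if ref_row not in aln.ids:
        raise ValueError(f"reference row {ref_row!r} not in alignment")
    if anchor < 1:
        raise ValueError("anchor coordinate must be >= 1")
    row = aln.row(ref_row)
    nongap = row != GAP
    n_bases = int(nongap.sum())
    if n_bases == 0:
        raise ValueError(f"reference row {ref_row!r} is all gaps")
    offsets = np.cumsum(nongap) - 1  # ungapped index per column
    col_coord = np.zeros(aln.n_columns, dtype=np.int64)
    if orientation == "forward":
        col_coord[nongap] = anchor + offsets[nongap]
        span_start, span_end = anchor, anchor + n_bases - 1
    else:
        col_coord[nongap] = anchor - offsets[nongap]
        span_start, span_end = anchor - n_bases + 1, anchor
    if span_start < 1:
        raise ValueError(
            f"reverse map with anchor {anchor} runs below coordinate 1"
        )
    coord_col = np.zeros(span_end - span_start + 1, dtype=np.int64)
    mapped_cols = np.nonzero(nongap)[0] + 1
    coord_col[col_coord[nongap] - span_start] = mapped_cols
    return ColumnMap(
        ref_id=ref_row,
        anchor=anchor,
        orientation=orientation,
        _col_coord=col_coord,
        _coord_col=coord_col,
        span_start=span_start,
        span_end=span_end,
    )


def write_sites_bed(
    sites: Iterable,
    column_map: ColumnMap,
    path: str | Path,
    chrom: str = "ref",
) -> int:
    """Write typed sites as BED6, one length-1 interval per mapped site.

    ``sites`` may be any objects with ``column`` and ``type_label``
    attributes (e.g. :class:`traitscan.classify.TypedSite`).  Unmapped sites
    are skipped with a logged count.  Returns the number of lines written.
    """
    strand = "+" if column_map.orientation == "forward" else "-"
    n_written = n_skipped = 0
    with open(path, "w") as fh:
        for site in sites:
            coord = column_map.coord_of_column(site.column)
            if coord is None:
                n_skipped += 1
                continue
            name = getattr(site, "type_label", None) or "untyped"
            fh.write(f"{chrom}\t{coord - 1}\t{coord}\t{name}\t0\t{strand}\n")
            n_written += 1
    if n_skipped:
        logger.warning("%d unmapped sites skipped in BED output", n_skipped)
    return n_written


def write_site_report(sites: Sequence, path: str | Path) -> None:
    """Write the typed-site TSV (site type, small/large allele, coordinate,
    feature, alignment column)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "site_type": s.type_label if s.type_label else "none",
                "small_allele": s.allele_b if s.allele_b else "NA",
                "large_allele": s.allele_a if s.allele_a else "NA",
                "coordinate": s.coordinate if s.coordinate is not None else "NA",
                "feature": s.feature if s.feature is not None else "NA",
                "alignment_column": s.column,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "site_type",
            "small_allele",
            "large_allele",
            "coordinate",
            "feature",
            "alignment_column",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file into (chrom, start, end, name) tuples (0-based
    half-open, as stored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer interval") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            out.append((parts[0], start, end, name))
    return out
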