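"""Clade-pattern typing of alignment columns and feature annotation.

A :class:`CladePattern` names a bipartition of species: a column realizes
the pattern when every group-A species carries one shared allele, every
group-B species carries a different shared allele, and both alleles are
non-missing.  Species outside both groups (outgroups) are ignored.  This is
how "type 1" sites (three large whales — blue, minke, sperm — versus all
other artiodactyls) and "type 2" sites (the four largest whales plus
terrestrial artiodactyls versus the smaller cetaceans) are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigError, FormatError
from .scan import ColumnData


@dataclass(frozen=True)
class CladePattern:
    """A named species bipartition defining a site type.

    ``group_a`` is conventionally the large-bodied side (its shared allele is
    reported as the "large allele"), ``group_b`` the small-bodied side.
    """

    name: str
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self):
        ga = frozenset(self.group_a)
        gb = frozenset(self.group_b)
        object.__setattr__(self, "group_a", ga)
        object.__setattr__(self, "group_b", gb)
        if not ga or not gb:
            raise ConfigError(f"pattern {self.name!r}: both groups must be non-empty")
        if ga & gb:
            raise ConfigError(
                f"pattern {self.name!r}: groups overlap: {sorted(ga & gb)}"
            )

    def validate_species(self, species: Iterable[str]) -> None:
        known = set(species)
        unknown = (self.group_a | self.group_b) - known
        if unknown:
            raise ConfigError(
                f"pattern {self.name!r} references unknown species: "
                f"{sorted(unknown)}"
            )


@dataclass
class TypedSite:
    """A column with (possibly) a clade-pattern type call."""

    column: int
    type_label: str | None = None
    allele_a: str | None = None
    allele_b: str | None = None
    coordinate: int | None = None
    chrom: str | None = None
    feature: str | None = None
    flags: frozenset = frozenset()
    notes: str = ""


def classify_column(
    col: ColumnData, patterns: Sequence[CladePattern]
) -> TypedSite:
    """Assign the first matching clade pattern (config order) to a column.

    A pattern matches when group A is allele-uniform, group B is
    allele-uniform, both alleles are non-missing, and they differ.  Missing
    alleles inside a group produce no call for that pattern and a
    "missing-data" note.  The call depends only on the allele partition, not
    on which nucleotides realize it.
    """
    alleles = dict(zip(col.species, col.alleles))
    notes: list[str] = []
    for pat in patterns:
        pat.validate_species(col.species)
        a_alleles = {alleles.get(s) for s in pat.group_a}
        b_alleles = {alleles.get(s) for s in pat.group_b}
        if None in a_alleles or None in b_alleles:
            notes.append(f"{pat.name}: missing-data")
            continue
        if len(a_alleles) == 1 and len(b_alleles) == 1:
            (a,) = a_alleles
            (b,) = b_alleles
            if a != b:
                return TypedSite(
                    column=col.column,
                    type_label=pat.name,
                    allele_a=a,
                    allele_b=b,
                    notes="; ".join(notes),
                )
    return TypedSite(column=col.column, notes="; ".join(notes))


def classify_columns(
    aln, columns: Iterable[int], patterns: Sequence[CladePattern]
) -> list[TypedSite]:
    """Classify a set of 1-based columns of an alignment."""
    return [
        classify_column(ColumnData.from_alignment(aln, c), patterns)
        for c in columns
    ]


UNANNOTATED = "intergenic/unannotated"


def annotate_features(
    sites: Sequence[TypedSite],
    features: Sequence[tuple[str, int, int, str]],
    chrom: str | None = None,
) -> list[TypedSite]:
    """Label each site with overlapping feature names (sorted, "; "-joined).

    ``features`` are BED-style (chrom, start, end, name) with 0-based
    half-open intervals, e.g. from :func:`traitscan.alignio.read_bed`.
    Sites without a mapped coordinate keep feature "NA"; mapped sites with no
    overlap get ``intergenic/unannotated``.  Sites are returned in input
    order with features filled in place.
    """
    for f in features:
        if len(f) != 4 or f[2] < f[1]:
            raise FormatError(f"malformed feature interval: {f!r}")
    for site in sites:
        if site.coordinate is None:
            site.feature = "NA"
            continue
        site_chrom = site.chrom if site.chrom is not None else chrom
        pos0 = site.coordinate - 1  # 1-based coordinate -> 0-based position
        names = sorted(
            {
                name
                for (fchrom, start, end, name) in features
                if (site_chrom is None or fchrom == site_chrom)
                and start <= pos0 < end
            }
        )
        site.feature = "; ".join(names) if names else UNANNOTATED
    return list(sites)
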