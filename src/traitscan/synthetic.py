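"""Synthetic alignments, trait tables and genotype tracks with known truth.

The generator emulates the statistical structure the downstream analyses
assume: ~29 artiodactyl-like species split into aquatic and terrestrial
habitats with clade-structured log body mass spanning tens of kilograms to
~150,000 kg; an alignment with i.i.d. background polymorphism, gaps,
low-complexity repeat blocks and planted clade-pattern columns; and
multi-scaffold diploid genotype tracks with overdispersed (negative
binomial) depth around 30-45x, background heterozygosity ~1e-3 per site and
planted low-heterozygosity (ROH) segments.

A single root seed deterministically derives independent streams for the
three generators, so adding plants or changing track parameters never
perturbs the other artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignio import AlignmentMatrix, BASES
from .classify import CladePattern
from .errors import ConfigError
from .popgen import GenotypeTrack

# stream indices spawned from the root seed
_STREAM_TRAITS, _STREAM_ALIGNMENT, _STREAM_TRACK = 0, 1, 2


@dataclass(frozen=True)
class PlantSpec:
    """A column planted to realize a clade pattern exactly."""

    column: int  # 1-based
    pattern: str  # CladePattern name
    allele_a: str  # shared allele of group A
    allele_b: str  # shared allele of group B

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ConfigError(
                f"plant at column {self.column}: alleles must differ"
            )
        for a in (self.allele_a, self.allele_b):
            if a not in BASES:
                raise ConfigError(f"plant allele {a!r} not in {BASES}")


@dataclass(frozen=True)
class LowComplexityBlock:
    """A tandem-repeat block with elevated gap rate (alignment artifact)."""

    start: int  # 1-based first column
    length: int
    unit: str = "AT"

    def columns(self) -> range:
        return range(self.start, self.start + self.length)


@dataclass(frozen=True)
class RohSegment:
    """A planted low-heterozygosity genomic segment."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    residual_het_rate: float = 0.0


@dataclass
class SimConfig:
    """All knobs of the three generators (see module docstring for defaults'
    rationale)."""

    seed: int = 0
    # --- species / traits ---
    species: list[str] = field(default_factory=list)
    habitat: dict[str, str] = field(default_factory=dict)
    clade_assignments: dict[str, str] = field(default_factory=dict)
    mass_log_means: dict[str, float] = field(default_factory=dict)
    mass_log_sd: float = 0.6
    # --- alignment ---
    n_columns: int = 20_000
    background_minor_freq: float = 0.05
    gap_rate: float = 0.02
    low_complexity_blocks: list[LowComplexityBlock] = field(default_factory=list)
    lc_gap_rate_factor: float = 5.0
    plants: list[PlantSpec] = field(default_factory=list)
    patterns: list[CladePattern] = field(default_factory=list)
    #: assign background minor alleles clade-wise instead of i.i.d. — creates
    #: confounded nulls for probing the stratified permutation scheme
    clade_wise_minor: bool = False
    # --- genotype track ---
    n_scaffolds: int = 2
    scaffold_length: int = 2_000_000
    mean_depth: float = 40.0
    depth_dispersion: float = 3.0  # negative-binomial size parameter
    background_het_rate: float = 1e-3
    callable_fraction: float = 0.9
    roh_segments: list[RohSegment] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def pattern_by_name(self, name: str) -> CladePattern:
        for p in self.patterns:
            if p.name == name:
                return p
        raise ConfigError(f"plant references undefined pattern {name!r}")

    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    def validate(self) -> None:
        if self.n_species < 4:
            raise ConfigError("need at least 4 species")
        habs = set(self.habitat.get(s) for s in self.species)
        if not {"aquatic", "terrestrial"} <= habs:
            raise ConfigError("need at least one species per habitat")
        if self.mass_log_sd < 0:
            raise ConfigError("mass_log_sd must be non-negative")
        for s in self.species:
            clade = self.clade_assignments.get(s)
            if clade is None or clade not in self.mass_log_means:
                raise ConfigError(f"species {s!r} lacks a clade with a mass mean")
        for p in (
            self.background_minor_freq,
            self.gap_rate,
            self.background_het_rate,
            self.callable_fraction,
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        cols = [p.column for p in self.plants]
        if len(set(cols)) != len(cols):
            raise ConfigError("planted columns must be pairwise distinct")
        lc_cols = set()
        for b in self.low_complexity_blocks:
            if b.start < 1 or b.start + b.length - 1 > self.n_columns:
                raise ConfigError("low-complexity block outside alignment")
            lc_cols.update(b.columns())
        for p in self.plants:
            if not 1 <= p.column <= self.n_columns:
                raise ConfigError(f"plant column {p.column} outside alignment")
            if p.column in lc_cols:
                raise ConfigError(
                    f"plant column {p.column} collides with a low-complexity block"
                )
            self.pattern_by_name(p.pattern).validate_species(self.species)
        scafs = set(self.scaffold_names())
        by_scaf: dict[str, list[RohSegment]] = {}
        for seg in self.roh_segments:
            if seg.scaffold not in scafs:
                raise ConfigError(f"ROH segment on unknown scaffold {seg.scaffold}")
            if seg.start < 1 or seg.end > self.scaffold_length or seg.start > seg.end:
                raise ConfigError(
                    f"ROH segment {seg.scaffold}:{seg.start}-{seg.end} outside bounds"
                )
            by_scaf.setdefault(seg.scaffold, []).append(seg)
        for scaf, segs in by_scaf.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ConfigError(f"overlapping ROH segments on {scaf}")

    def streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


@dataclass
class TruthTable:
    """Ground truth of the planted signal (sites and ROH segments)."""

    planted_sites: pd.DataFrame  # column, pattern, allele_a, allele_b
    planted_roh: pd.DataFrame  # scaffold, start, end, residual_het_rate

    def write(self, sites_path: str | Path, roh_path: str | Path) -> None:
        self.planted_sites.to_csv(sites_path, sep="\t", index=False)
        self.planted_roh.to_csv(roh_path, sep="\t", index=False)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard study-scale configuration: 29 species (11 aquatic, 18
    terrestrial), clade-structured masses from ~50 kg to ~150,000 kg, and
    type-1/type-2 clade patterns over the cetacean clades."""
    large_baleen = ["blue_whale", "minke_whale"]
    sperm = ["sperm_whale"]
    orca = ["orca"]
    dolphins = [f"dolphin_{i}" for i in range(1, 8)]
    small_toothed = orca + dolphins
    terrestrial_large = [f"bovid_{i}" for i in range(1, 10)]
    terrestrial_small = [f"cervid_{i}" for i in range(1, 10)]
    species = large_baleen + sperm + small_toothed + terrestrial_large + terrestrial_small
    habitat = {s: "aquatic" for s in large_baleen + sperm + small_toothed}
    habitat.update({s: "terrestrial" for s in terrestrial_large + terrestrial_small})
    clades = {}
    clades.update({s: "large_baleen" for s in large_baleen})
    clades.update({s: "sperm" for s in sperm})
    clades.update({s: "orca" for s in orca})
    clades.update({s: "small_toothed" for s in dolphins})
    clades.update({s: "terrestrial_large" for s in terrestrial_large})
    clades.update({s: "terrestrial_small" for s in terrestrial_small})
    # the orca is the largest dolphin, comparable in mass to a minke whale,
    # so it carries its own mass scale rather than the small-dolphin one
    mass_log_means = {
        "large_baleen": math.log(50_000.0),  # blue/minke whale scale
        "sperm": math.log(40_000.0),
        "orca": math.log(4_500.0),
        "small_toothed": math.log(300.0),
        "terrestrial_large": math.log(500.0),
        "terrestrial_small": math.log(60.0),
    }
    three_large = frozenset(large_baleen + sperm)
    four_largest = frozenset(large_baleen + sperm + ["orca"])
    small_cetaceans = frozenset(s for s in small_toothed if s != "orca")
    patterns = [
        CladePattern(
            name="type1",
            group_a=three_large,
            group_b=frozenset(species) - three_large,
        ),
        CladePattern(
            name="type2",
            group_a=four_largest | frozenset(terrestrial_large + terrestrial_small),
            group_b=small_cetaceans,
        ),
    ]
    cfg = SimConfig(
        seed=seed,
        species=species,
        habitat=habitat,
        clade_assignments=clades,
        mass_log_means=mass_log_means,
        patterns=patterns,
        roh_segments=[RohSegment("scaffold_1", 700_001, 1_300_000, 0.0)],
    )
    cfg = replace(cfg, **overrides)
    return cfg


def default_plants(config: SimConfig, n_type1: int = 7, n_type2: int = 5,
                   spacing: int | None = None) -> list[PlantSpec]:
    """Evenly spaced planted columns alternating alleles, avoiding
    low-complexity blocks."""
    lc = set()
    for b in config.low_complexity_blocks:
        lc.update(b.columns())
    n = n_type1 + n_type2
    step = spacing if spacing is not None else max(1, config.n_columns // (n + 1))
    plants = []
    col = step
    pairs = [("T", "C"), ("C", "T"), ("G", "A"), ("A", "G")]
    for i in range(n):
        while col in lc:
            col += 1
        a, b = pairs[i % len(pairs)]
        name = "type1" if i < n_type1 else "type2"
        plants.append(PlantSpec(column=col, pattern=name, allele_a=a, allele_b=b))
        col += step
    return plants


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_trait_table(config: SimConfig) -> pd.DataFrame:
    """Species trait table: clade-mean log mass plus Gaussian noise.

    Deterministic given the config seed; the trait stream is independent of
    the alignment and track streams.
    """
    config.validate()
    rng = config.streams()[_STREAM_TRAITS]
    rows = []
    noise = rng.normal(0.0, config.mass_log_sd, size=config.n_species)
    for i, s in enumerate(config.species):
        clade = config.clade_assignments[s]
        log_mass = config.mass_log_means[clade] + noise[i]
        rows.append(
            {
                "species": s,
                "mass_kg": math.exp(log_mass),
                "habitat": config.habitat[s],
                "clade": clade,
                "log_mass": log_mass,
            }
        )
    return pd.DataFrame(rows)


def simulate_alignment(
    traits: pd.DataFrame, config: SimConfig
) -> tuple[AlignmentMatrix, TruthTable]:
    """Alignment over {A,C,G,T,-} with background polymorphism, gaps,
    low-complexity blocks and exactly realized planted pattern columns."""
    config.validate()
    if set(traits["species"]) != set(config.species):
        raise ConfigError("trait table species differ from config species")
    rng = config.streams()[_STREAM_ALIGNMENT]
    n_sp, n_col = config.n_species, config.n_columns
    species = list(config.species)
    sp_index = {s: i for i, s in enumerate(species)}
    base_arr = np.array(list(BASES))

    # background: per column a major allele; each species flips to the minor
    # allele with background_minor_freq
    major = rng.integers(0, 4, size=n_col)
    minor_shift = rng.integers(1, 4, size=n_col)
    minor = (major + minor_shift) % 4
    if config.clade_wise_minor:
        # whole clades flip together: the minor allele marks a random clade
        clades = sorted(set(config.clade_assignments.values()))
        clade_of_sp = np.array(
            [clades.index(config.clade_assignments[s]) for s in species]
        )
        flip_clade = rng.integers(0, len(clades), size=n_col)
        # match the i.i.d. expected minor fraction: a species is in the
        # flipped clade with prob 1/len(clades)
        q = min(1.0, config.background_minor_freq * len(clades))
        col_has_minor = rng.random(n_col) < q
        is_minor = (clade_of_sp[:, None] == flip_clade[None, :]) & col_has_minor[None, :]
    else:
        is_minor = rng.random((n_sp, n_col)) < config.background_minor_freq
    codes = np.where(is_minor, minor[None, :], major[None, :])
    chars = base_arr[codes]

    # gaps
    gap_mask = rng.random((n_sp, n_col)) < config.gap_rate
    chars[gap_mask] = "-"

    # low-complexity blocks: tandem repeat of the unit, elevated gap rate
    lc_gap = min(1.0, config.gap_rate * config.lc_gap_rate_factor)
    for blk in config.low_complexity_blocks:
        cols = np.array(list(blk.columns())) - 1
        unit = blk.unit.upper()
        pattern = np.array([unit[(c - (blk.start - 1)) % len(unit)] for c in cols])
        chars[:, cols] = pattern[None, :]
        g = rng.random((n_sp, len(cols))) < lc_gap
        chars[:, cols] = np.where(g, "-", chars[:, cols])

    # planted columns: realize the pattern exactly, no gaps
    truth_rows = []
    for plant in config.plants:
        pat = config.pattern_by_name(plant.pattern)
        c = plant.column - 1
        chars[:, c] = plant.allele_b
        for s in pat.group_a:
            chars[sp_index[s], c] = plant.allele_a
        for s in pat.group_b:
            chars[sp_index[s], c] = plant.allele_b
        truth_rows.append(
            {
                "column": plant.column,
                "pattern": plant.pattern,
                "allele_a": plant.allele_a,
                "allele_b": plant.allele_b,
            }
        )
    truth = TruthTable(
        planted_sites=pd.DataFrame(
            truth_rows, columns=["column", "pattern", "allele_a", "allele_b"]
        ),
        planted_roh=pd.DataFrame(
            columns=["scaffold", "start", "end", "residual_het_rate"]
        ),
    )
    return AlignmentMatrix(ids=species, chars=chars), truth


def simulate_genotype_track(config: SimConfig) -> tuple[GenotypeTrack, TruthTable]:
    """Multi-scaffold genotype track with NB depth and planted ROH segments.

    Callable sites are a Bernoulli(callable_fraction) thinning of each
    scaffold; each callable site is heterozygous with the background rate
    (or the segment's residual rate inside a planted ROH).  Depth is
    negative binomial with the configured mean and dispersion (size)
    parameter.
    """
    config.validate()
    rng = config.streams()[_STREAM_TRACK]
    frames = []
    lengths: dict[str, int] = {}
    segs_by_scaf: dict[str, list[RohSegment]] = {}
    for seg in config.roh_segments:
        segs_by_scaf.setdefault(seg.scaffold, []).append(seg)
    p_nb = config.depth_dispersion / (config.depth_dispersion + config.mean_depth)
    for scaf in config.scaffold_names():
        L = config.scaffold_length
        lengths[scaf] = L
        callable_mask = rng.random(L) < config.callable_fraction
        pos = np.nonzero(callable_mask)[0] + 1
        het_rate = np.full(len(pos), config.background_het_rate)
        for seg in segs_by_scaf.get(scaf, []):
            inside = (pos >= seg.start) & (pos <= seg.end)
            het_rate[inside] = seg.residual_het_rate
        is_het = rng.random(len(pos)) < het_rate
        depth = rng.negative_binomial(config.depth_dispersion, p_nb, size=len(pos))
        ref = rng.integers(0, 4, size=len(pos))
        alt = (ref + rng.integers(1, 4, size=len(pos))) % 4
        base_arr = np.array(list(BASES))
        a1 = base_arr[ref]
        a2 = np.where(is_het, base_arr[alt], a1)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "pos": pos,
                    "gt": np.where(is_het, "het", "hom"),
                    "depth": depth,
                    "a1": a1,
                    "a2": a2,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold", "pos", "gt", "depth", "a1", "a2"]
    )
    truth = TruthTable(
        planted_sites=pd.DataFrame(columns=["column", "pattern", "allele_a", "allele_b"]),
        planted_roh=pd.DataFrame(
            [
                {
                    "scaffold": s.scaffold,
                    "start": s.start,
                    "end": s.end,
                    "residual_het_rate": s.residual_het_rate,
                }
                for s in config.roh_segments
            ],
            columns=["scaffold", "start", "end", "residual_het_rate"],
        ),
    )
    return GenotypeTrack(sites=sites, scaffold_lengths=lengths), truth
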