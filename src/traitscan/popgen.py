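"""Windowed heterozygosity, ROH calling, Froh, pseudodiploid construction.

Inputs are per-site diploid genotype calls with read depth
(:class:`GenotypeTrack`), read from VCF or a 4-column TSV dialect.  The
stages mirror a standard single-genome diversity workflow:

* depth filter — keep sites within [mean/3, 2 x mean] coverage;
* heterozygosity in non-overlapping 1-Mb windows (het = n_het / n_called);
* ROH — runs of >= 25 consecutive 20-kb windows with per-window
  heterozygosity <= 2.5%, summarized as Froh (fraction of the assessed
  genome in runs >= 500 kb) and a run-length histogram;
* pseudodiploid track — one allele sampled per site from each of two
  genomes; its coalescence profile dates the loss of gene flow between the
  source populations;
* psmcfa export — 100-bp bins coded K/T/N for the externally run PSMC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GT_VALUES = ("hom", "het")

#: PSMC settings used downstream of the psmcfa export; recorded in output
#: metadata only — the PSMC model itself is an external program.
PSMC_METADATA = {
    "generation_time_years": 30.8,
    "mutation_rate_per_bp_per_generation": 1.58e-8,
    "max_coalescent_time_t": 15,
}


@dataclass
class GenotypeTrack:
    """Ordered per-site genotype calls for one or more scaffolds.

    ``sites`` columns: scaffold (str), pos (1-based int), gt ("hom"/"het"),
    depth (int); optional allele columns a1/a2 (single characters) carried
    when the track feeds pseudodiploid construction.
    """

    sites: pd.DataFrame
    scaffold_lengths: dict[str, int]

    def __post_init__(self):
        required = {"scaffold", "pos", "gt", "depth"}
        missing = required - set(self.sites.columns)
        if missing:
            raise FormatError(f"track missing columns {sorted(missing)}")
        bad_gt = ~self.sites["gt"].isin(GT_VALUES)
        if bad_gt.any():
            raise FormatError(
                f"invalid gt values: {self.sites.loc[bad_gt, 'gt'].unique()[:5]}"
            )
        for scaf, grp in self.sites.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) and not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on {scaf}"
                )
            if scaf not in self.scaffold_lengths:
                raise ValidationError(f"no length for scaffold {scaf}")
            if len(pos) and pos[-1] > self.scaffold_lengths[scaf]:
                raise ValidationError(
                    f"{scaf}: position {pos[-1]} beyond length "
                    f"{self.scaffold_lengths[scaf]}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_het(self) -> int:
        return int((self.sites["gt"] == "het").sum())

    def mean_depth(self) -> float:
        if not len(self.sites):
            raise ValidationError("empty track has no mean depth")
        return float(self.sites["depth"].mean())

    # ---- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for scaf, length in self.scaffold_lengths.items():
                fh.write(f"#scaffold_length\t{scaf}\t{length}\n")
            cols = ["scaffold", "pos", "gt", "depth"]
            if {"a1", "a2"} <= set(self.sites.columns):
                cols += ["a1", "a2"]
            self.sites[cols].to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTrack":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            skip = 0
            for line in fh:
                if line.startswith("#scaffold_length"):
                    _, scaf, length = line.rstrip("\n").split("\t")
                    lengths[scaf] = int(length)
                    skip += 1
                else:
                    break
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(sites=df, scaffold_lengths=lengths)

    @classmethod
    def from_vcf(cls, path: str | Path, sample: str | None = None) -> "GenotypeTrack":
        """Read genotype class and depth from a VCF (GT and DP FORMAT fields)."""
        import pysam

        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        sname = sample if sample is not None else samples[0]
        lengths = {c: vf.header.contigs[c].length for c in vf.header.contigs}
        if any(l is None for l in lengths.values()):
            raise FormatError(f"{path}: contig lengths missing from VCF header")
        rows = []
        for rec in vf:
            call = rec.samples[sname]
            gt = call.get("GT")
            if gt is None or None in gt:
                continue
            alleles = [rec.alleles[i] for i in gt]
            klass = "het" if len(set(alleles)) > 1 else "hom"
            dp = call.get("DP")
            rows.append(
                {
                    "scaffold": rec.chrom,
                    "pos": rec.pos,
                    "gt": klass,
                    "depth": int(dp) if dp is not None else 0,
                    "a1": alleles[0],
                    "a2": alleles[-1],
                }
            )
        return cls(sites=pd.DataFrame(rows), scaffold_lengths=lengths)

    def to_vcf(self, path: str | Path, sample: str = "sample1") -> None:
        """Write the track as a minimal single-sample VCF (GT and DP)."""
        import pysam

        header = pysam.VariantHeader()
        for scaf, length in self.scaffold_lengths.items():
            header.contigs.add(scaf, length=length)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.add_sample(sample)
        has_alleles = {"a1", "a2"} <= set(self.sites.columns)
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for row in self.sites.itertuples(index=False):
                if has_alleles:
                    a1, a2 = row.a1, row.a2
                else:
                    a1, a2 = ("A", "C") if row.gt == "het" else ("A", "A")
                ref = a1
                alts = tuple(sorted({a for a in (a1, a2) if a != ref}))
                if not alts:
                    # htslib requires >=2 alleles; hom sites carry a dummy ALT
                    alts = ("C",) if ref != "C" else ("A",)
                rec = out.new_record(
                    contig=row.scaffold,
                    start=row.pos - 1,
                    stop=row.pos,
                    alleles=(ref,) + alts,
                )
                idx = {a: i for i, a in enumerate(rec.alleles)}
                rec.samples[sample]["GT"] = (idx[a1], idx[a2])
                rec.samples[sample]["DP"] = int(row.depth)
                out.write(rec)


# ---------------------------------------------------------------------------
# depth filter
# ---------------------------------------------------------------------------

def filter_by_depth(
    track: GenotypeTrack, mean_depth: float | None = None
) -> GenotypeTrack:
    """Keep sites with depth in the boundary-inclusive band
    [mean/3, 2 x mean].

    ``mean_depth`` defaults to the mean over the unfiltered input; the bounds
    are frozen at that value, so re-applying the filter with the same mean is
    the identity (idempotence).
    """
    if not len(track.sites):
        return GenotypeTrack(
            sites=track.sites.copy(), scaffold_lengths=dict(track.scaffold_lengths)
        )
    mean = track.mean_depth() if mean_depth is None else float(mean_depth)
    if mean <= 0:
        raise ValidationError("mean depth must be positive")
    d = track.sites["depth"].to_numpy()
    keep = (d >= mean / 3.0) & (d <= 2.0 * mean)
    return GenotypeTrack(
        sites=track.sites.loc[keep].reset_index(drop=True),
        scaffold_lengths=dict(track.scaffold_lengths),
    )


# ---------------------------------------------------------------------------
# windowed heterozygosity
# ---------------------------------------------------------------------------

def window_heterozygosity(
    track: GenotypeTrack, window_size: int = 1_000_000
) -> pd.DataFrame:
    """Heterozygosity (n_het / n_called) in non-overlapping tiling windows.

    Every scaffold is tiled from position 1; the final, possibly shorter
    window is included and flagged ``partial``.  Windows with no called
    sites report het = NaN.  Columns: scaffold, start, end (1-based
    inclusive), n_called, n_het, het, partial.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    frames = []
    for scaf, length in track.scaffold_lengths.items():
        n_win = max(1, -(-length // window_size)) if length >= 1 else 0
        if n_win == 0:
            continue
        starts = np.arange(n_win, dtype=np.int64) * window_size + 1
        ends = np.minimum(starts + window_size - 1, length)
        sub = track.sites[track.sites["scaffold"] == scaf]
        widx = (sub["pos"].to_numpy() - 1) // window_size
        n_called = np.bincount(widx, minlength=n_win).astype(np.int64)
        n_het = np.bincount(
            widx, weights=(sub["gt"] == "het").to_numpy(float), minlength=n_win
        ).astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": starts,
                    "end": ends,
                    "n_called": n_called,
                    "n_het": n_het,
                    "het": het,
                    "partial": ends - starts + 1 < window_size,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["scaffold", "start", "end", "n_called", "n_het", "het", "partial"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------

@dataclass
class ROHRun:
    """A maximal run of consecutive low-heterozygosity windows."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    n_windows: int
    mean_het: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_roh(
    track: GenotypeTrack,
    window_size: int = 20_000,
    min_windows: int = 25,
    het_threshold: float = 0.025,
    score: str = "fraction",
    empty_windows_qualify: bool = False,
) -> list[ROHRun]:
    """Call runs of homozygosity on non-overlapping windows.

    A window qualifies when its heterozygosity score is <= ``het_threshold``;
    maximal stretches of >= ``min_windows`` consecutive qualifying windows
    become runs.  ``score='fraction'`` uses n_het / n_called;
    ``score='per_kb'`` uses n_het per kb of window span.  Windows with no
    called sites qualify only if ``empty_windows_qualify`` (by default the
    absence of calls is not treated as evidence of homozygosity and such
    windows break runs).
    """
    if window_size < 1 or min_windows < 1 or het_threshold < 0:
        raise ValueError("ROH thresholds must be positive")
    if score not in ("fraction", "per_kb"):
        raise ValueError(f"unknown score {score!r}")
    win = window_heterozygosity(track, window_size)
    runs: list[ROHRun] = []
    for scaf, grp in win.groupby("scaffold", sort=False):
        grp = grp.sort_values("start")
        if score == "fraction":
            s = grp["het"].to_numpy()
        else:
            span_kb = (grp["end"] - grp["start"] + 1).to_numpy() / 1000.0
            s = grp["n_het"].to_numpy() / span_kb
        called = grp["n_called"].to_numpy() > 0
        qual = np.where(called, s <= het_threshold, empty_windows_qualify)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n_het = grp["n_het"].to_numpy()
        n_called = grp["n_called"].to_numpy()
        i = 0
        n = len(qual)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            j = i
            while j < n and qual[j]:
                j += 1
            if j - i >= min_windows:
                tot_called = int(n_called[i:j].sum())
                tot_het = int(n_het[i:j].sum())
                runs.append(
                    ROHRun(
                        scaffold=scaf,
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        n_windows=j - i,
                        mean_het=tot_het / tot_called if tot_called else 0.0,
                    )
                )
            i = j
    return runs


@dataclass
class RohSummary:
    """Froh and the run-length histogram over qualifying runs."""

    runs: list[ROHRun]
    froh: float
    min_length: int
    assessed_length: int
    bin_edges: list[float]
    bin_counts: list[int]
    longest: ROHRun | None
    #: Froh with no minimum run length, for comparison
    froh_all_runs: float = 0.0

    def to_dict(self) -> dict:
        return {
            "froh": self.froh,
            "froh_all_runs": self.froh_all_runs,
            "min_length": self.min_length,
            "assessed_length": self.assessed_length,
            "n_runs": len(self.runs),
            "n_runs_over_min_length": int(
                sum(r.length >= self.min_length for r in self.runs)
            ),
            "bin_edges": self.bin_edges,
            "bin_counts": self.bin_counts,
            "longest_run": None
            if self.longest is None
            else {
                "scaffold": self.longest.scaffold,
                "start": self.longest.start,
                "end": self.longest.end,
                "length": self.longest.length,
            },
        }


#: default run-length histogram bin edges (bp); right edge open-ended
DEFAULT_ROH_BINS = [
    500_000,
    1_000_000,
    1_500_000,
    2_000_000,
    2_500_000,
    3_000_000,
    4_000_000,
    5_000_000,
    float("inf"),
]


def summarize_roh(
    runs: Sequence[ROHRun],
    assessed_length: int,
    min_length: int = 500_000,
    bins: Sequence[float] | None = None,
) -> RohSummary:
    """Froh (>= ``min_length`` runs over assessed length) and length bins.

    ``assessed_length`` should be the callable/assessed genome span the runs
    were searched in; Froh over all runs regardless of length is reported
    alongside for comparison.
    """
    if assessed_length <= 0:
        raise ValidationError("assessed_length must be positive")
    total_all = sum(r.length for r in runs)
    if assessed_length < total_all:
        raise ValidationError("assessed_length smaller than total run length")
    edges = list(bins) if bins is not None else list(DEFAULT_ROH_BINS)
    qualifying = [r for r in runs if r.length >= min_length]
    counts = [0] * (len(edges) - 1)
    for r in qualifying:
        for b in range(len(edges) - 1):
            if edges[b] <= r.length < edges[b + 1]:
                counts[b] += 1
                break
    longest = max(runs, key=lambda r: r.length, default=None)
    return RohSummary(
        runs=list(runs),
        froh=sum(r.length for r in qualifying) / assessed_length,
        min_length=min_length,
        assessed_length=assessed_length,
        bin_edges=edges,
        bin_counts=counts,
        longest=longest,
        froh_all_runs=total_all / assessed_length,
    )


def write_roh_bed(runs: Sequence[ROHRun], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(runs, 1):
            fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\tROH_{i}\t0\t+\n")


def write_roh_summary(summary: RohSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pseudodiploid
# ---------------------------------------------------------------------------

def make_pseudodiploid(
    track_a: GenotypeTrack, track_b: GenotypeTrack, seed: int
) -> GenotypeTrack:
    """Build a pseudodiploid track by sampling one allele per genome per site.

    Sites are intersected on positions called in both inputs (both tracks
    must carry a1/a2 allele columns).  At each shared site one allele is
    drawn uniformly from A's genotype and one from B's; the pseudodiploid
    site is heterozygous iff the two draws differ.  Deterministic given
    ``seed``.
    """
    for name, tr in (("A", track_a), ("B", track_b)):
        if not {"a1", "a2"} <= set(tr.sites.columns):
            raise ValidationError(f"track {name} lacks allele columns a1/a2")
    a = track_a.sites.set_index(["scaffold", "pos"])
    b = track_b.sites.set_index(["scaffold", "pos"])
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        logger.warning("pseudodiploid: no shared called sites")
        empty = track_a.sites.iloc[0:0].copy()
        return GenotypeTrack(sites=empty, scaffold_lengths={})
    a = a.loc[shared]
    b = b.loc[shared]
    rng = np.random.default_rng(seed)
    pick_a = rng.integers(0, 2, size=len(shared))
    pick_b = rng.integers(0, 2, size=len(shared))
    allele_a = np.where(pick_a == 0, a["a1"].to_numpy(), a["a2"].to_numpy())
    allele_b = np.where(pick_b == 0, b["a1"].to_numpy(), b["a2"].to_numpy())
    het = allele_a != allele_b
    depth = ((a["depth"].to_numpy() + b["depth"].to_numpy()) // 2).astype(int)
    df = pd.DataFrame(
        {
            "scaffold": [s for s, _ in shared],
            "pos": [p for _, p in shared],
            "gt": np.where(het, "het", "hom"),
            "depth": depth,
            "a1": allele_a,
            "a2": allele_b,
        }
    ).sort_values(["scaffold", "pos"], kind="stable").reset_index(drop=True)
    # lengths kept for every shared scaffold, with or without surviving sites
    lengths = {
        s: min(track_a.scaffold_lengths[s], track_b.scaffold_lengths[s])
        for s in set(track_a.scaffold_lengths) & set(track_b.scaffold_lengths)
    }
    return GenotypeTrack(sites=df, scaffold_lengths=lengths)


# ---------------------------------------------------------------------------
# psmcfa export
# ---------------------------------------------------------------------------

def write_psmcfa(
    track: GenotypeTrack,
    path: str | Path,
    bin_size: int = 100,
    min_called_fraction: float = 0.5,
    write_metadata: bool = True,
) -> dict[str, str]:
    """Write PSMC input: per ``bin_size``-bp bin, 'K' if it holds >= 1 het
    site, 'T' if fully homozygous, 'N' if called sites fall below
    ``min_called_fraction`` x bin_size.

    Returns the per-scaffold bin strings (also written as a FASTA-like file,
    60 characters per line).  PSMC run settings (generation time, mutation
    rate, t) are recorded in a JSON sidecar, not applied here.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out: dict[str, str] = {}
    with open(path, "w") as fh:
        for scaf, length in track.scaffold_lengths.items():
            n_bins = -(-length // bin_size)
            sub = track.sites[track.sites["scaffold"] == scaf]
            bidx = (sub["pos"].to_numpy() - 1) // bin_size
            n_called = np.bincount(bidx, minlength=n_bins)
            n_het = np.bincount(
                bidx, weights=(sub["gt"] == "het").to_numpy(float), minlength=n_bins
            )
            chars = np.where(
                n_called < min_called_fraction * bin_size,
                "N",
                np.where(n_het > 0, "K", "T"),
            )
            # a bin with a het site is informative even at low callability
            chars = np.where(n_het > 0, "K", chars)
            s = "".join(chars)
            out[scaf] = s
            fh.write(f">{scaf}\n")
            for j in range(0, len(s), 60):
                fh.write(s[j : j + 60] + "\n")
    if write_metadata:
        meta_path = Path(str(path) + ".json")
        with open(meta_path, "w") as fh:
            json.dump(
                {"bin_size": bin_size, "min_called_fraction": min_called_fraction,
                 "psmc": PSMC_METADATA},
                fh,
                indent=2,
            )
            fh.write("\n")
    return out
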