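"""Per-column trait-association scan with permutation-based FDR.

For every column of a species alignment two linear models of log body mass
are fitted: ``allele`` (mass ~ nucleotide) and ``allele+habitat``
(mass ~ habitat + nucleotide).  The reported p-value is the partial F-test
of the allele factor against the reduced model (intercept only, or
intercept + habitat).  For a biallelic column without covariate this
reduces to one-way ANOVA / the squared coefficient t-test.

False discovery rates for a p-value threshold t are estimated by permuting
species labels of the mass values — optionally stratified within habitat —
re-scanning, and dividing the average permuted hit count by the observed
hit count.

The engine is fully vectorized across columns: group structure (which
species carries which allele) is independent of the trait vector, so a
permutation re-scan costs a handful of ``bincount`` passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignio import BASES, AlignmentMatrix
from .errors import ValidationError

# flag vocabulary
FLAG_MONOMORPHIC = "monomorphic_skipped"
FLAG_SINGLETON = "singleton_class"
FLAG_ZERO_RESIDUAL = "zero_residual"
FLAG_LOW_COMPLEXITY = "low_complexity"
FLAG_COLLINEAR = "collinear_skipped"

MODELS = ("allele", "allele+habitat")

_RTOL_ZERO = 1e-12  # relative tolerance declaring a residual SS exactly zero
_H_TOL = 1e-9  # ||habitat residual||^2 below this => habitat collinear with allele


@dataclass
class ColumnData:
    """One alignment column after missing-data handling.

    Gaps, N and IUPAC ambiguity codes are treated as missing (the species is
    dropped from that column's model), not as a fifth allele class.
    """

    column: int
    species: list[str]
    alleles: list[str | None]

    @classmethod
    def from_alignment(cls, aln: AlignmentMatrix, column: int) -> "ColumnData":
        chars = aln.column(column)
        alleles = [c if c in BASES else None for c in chars]
        return cls(column=column, species=list(aln.ids), alleles=alleles)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.alleles:
            if a is not None:
                counts[a] = counts.get(a, 0) + 1
        return counts

    @property
    def n_used(self) -> int:
        return sum(a is not None for a in self.alleles)


@dataclass
class ColumnResult:
    """Model fit for one column; skipped columns carry no p-value."""

    column: int
    model: str
    F: float | None
    p_value: float | None
    df_num: int
    df_den: int
    n_used: int
    n_classes: int
    flags: frozenset = frozenset()


@dataclass
class FdrEstimate:
    """Permutation FDR at one p-value threshold.

    ``fdr`` is ``mean_hits_permuted / hits_original`` and is None
    (undefined, not zero) when no original hits exist.
    """

    threshold: float
    hits_original: int
    mean_hits_permuted: float
    fdr: float | None
    n_permutations: int
    n_runs: int
    per_run_mean_hits: list[float]
    per_run_fdr: list[float | None]
    stratified: bool
    model: str
    seed: int


def fdr_from_counts(hits_original: int, permuted_hits: Sequence[int]) -> float | None:
    """FDR = mean permuted hit count / original hit count (None if no hits)."""
    mean_perm = float(np.mean(permuted_hits)) if len(permuted_hits) else 0.0
    if hits_original == 0:
        return None
    return mean_perm / hits_original


class ScanEngine:
    """Precomputed column/group structure for fast repeated scans.

    All trait-independent quantities (allele class membership per column,
    habitat sums per class) are computed once; ``stats(y, with_habitat)``
    then evaluates every column's partial F for an arbitrary trait vector
    ``y`` in a few vectorized passes.
    """

    def __init__(self, aln: AlignmentMatrix, traits: pd.DataFrame):
        missing = set(aln.ids) - set(traits["species"])
        if missing:
            raise ValidationError(
                f"species absent from trait table: {sorted(missing)}"
            )
        t = traits.set_index("species").loc[aln.ids]
        self.species = list(aln.ids)
        self.y0 = t["log_mass"].to_numpy(dtype=float)
        if np.isnan(self.y0).any():
            raise ValidationError("missing log_mass in trait table")
        self.h = (t["habitat"].to_numpy() == "aquatic").astype(float)

        code = np.full(aln.chars.shape, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            code[aln.chars == b] = i
        n_sp, n_col = code.shape
        self.n_columns = n_col

        counts = np.stack([(code == i).sum(axis=0) for i in range(4)])  # (4, n_col)
        present = counts > 0
        self.k_all = present.sum(axis=0)  # allele classes per column
        self.n_used_all = (code >= 0).sum(axis=0)
        self.singleton_all = ((counts == 1) & present).any(axis=0)

        # candidate columns: >=2 allele classes; model-specific df checks later
        cols = np.nonzero(self.k_all >= 2)[0]
        self.cols = cols  # 0-based alignment column index per candidate
        m = len(cols)
        self.m = m
        if m == 0:
            return

        sub = code[:, cols]
        ent_c, ent_sp = np.nonzero((sub >= 0).T)  # sorted by candidate column
        ent_code = sub[ent_sp, ent_c]
        rank = np.cumsum(present[:, cols], axis=0) - 1  # (4, m)
        self.km = self.k_all[cols]
        goff = np.concatenate([[0], np.cumsum(self.km)[:-1]])
        self.G = int(self.km.sum())
        self.ent_sp = ent_sp
        self.ent_c = ent_c
        self.ent_gid = goff[ent_c] + rank[ent_code, ent_c]
        self.gid_col = np.repeat(np.arange(m), self.km)
        self.n_g = np.bincount(self.ent_gid, minlength=self.G).astype(float)
        self.n_c = np.bincount(ent_c, minlength=m).astype(float)

        ent_h = self.h[ent_sp]
        self.ent_h = ent_h
        self.Sh_g = np.bincount(self.ent_gid, weights=ent_h, minlength=self.G)
        Sh_c = np.bincount(ent_c, weights=ent_h, minlength=m)
        # squared norm of habitat residualized against the allele-class space
        h2 = Sh_c - np.bincount(
            self.gid_col, weights=self.Sh_g**2 / self.n_g, minlength=m
        )
        self.h2 = np.maximum(h2, 0.0)
        self.h_ok = self.h2 > _H_TOL

        self.ent_hid = 2 * ent_c + ent_h.astype(np.int64)
        self.n_ch = np.bincount(self.ent_hid, minlength=2 * m).astype(float)
        self.n_hab_present = (self.n_ch.reshape(m, 2) > 0).sum(axis=1)

    # ---- model degrees of freedom (trait-independent) -------------------
    def dfs(self, with_habitat: bool) -> tuple[np.ndarray, np.ndarray]:
        if not with_habitat:
            dfn = self.km - 1
            dfd = (self.n_c - self.km).astype(int)
        else:
            rank_full = self.km + self.h_ok.astype(int)
            dfn = rank_full - self.n_hab_present
            dfd = (self.n_c - rank_full).astype(int)
        return dfn.astype(int), dfd

    def tested_mask(self, with_habitat: bool) -> np.ndarray:
        """Candidate columns actually testable under the model (df >= 1).

        Depends only on alleles and habitat, never on trait values, so the
        tested set is identical between real and permuted scans.
        """
        dfn, dfd = self.dfs(with_habitat)
        return (dfn >= 1) & (dfd >= 1)

    # ---- F statistics for an arbitrary trait vector ---------------------
    def stats(self, y: np.ndarray, with_habitat: bool):
        """Return (F, RSS_full, RSS_red) over candidate columns for ``y``."""
        m, G = self.m, self.G
        w = y[self.ent_sp]
        Sy_g = np.bincount(self.ent_gid, weights=w, minlength=G)
        Syy_c = np.bincount(self.ent_c, weights=w * w, minlength=m)
        SSW = Syy_c - np.bincount(
            self.gid_col, weights=Sy_g**2 / self.n_g, minlength=m
        )
        SSW = np.maximum(SSW, 0.0)
        if not with_habitat:
            Sy_c = np.bincount(self.ent_c, weights=w, minlength=m)
            rss_red = np.maximum(Syy_c - Sy_c**2 / self.n_c, 0.0)
            rss_full = SSW
        else:
            Shy_c = np.bincount(self.ent_c, weights=w * self.ent_h, minlength=m)
            hty = Shy_c - np.bincount(
                self.gid_col, weights=self.Sh_g / self.n_g * Sy_g, minlength=m
            )
            gain = np.zeros(m)
            gain[self.h_ok] = hty[self.h_ok] ** 2 / self.h2[self.h_ok]
            rss_full = np.maximum(SSW - gain, 0.0)
            Sy_ch = np.bincount(self.ent_hid, weights=w, minlength=2 * m)
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(self.n_ch > 0, Sy_ch**2 / self.n_ch, 0.0)
            rss_red = np.maximum(Syy_c - contrib.reshape(m, 2).sum(axis=1), 0.0)
        dfn, dfd = self.dfs(with_habitat)
        ok = (dfn >= 1) & (dfd >= 1)
        F = np.full(m, np.nan)
        scale = np.maximum(rss_red, 1.0)
        zero_res = rss_full <= _RTOL_ZERO * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (rss_red - rss_full) / np.maximum(dfn, 1)
            den = rss_full / np.maximum(dfd, 1)
            F = np.where(ok, num / den, np.nan)
        # perfect fit: explained everything the reduced model left
        perfect = ok & zero_res & (rss_red > _RTOL_ZERO)
        F[perfect] = np.inf
        # degenerate: no variance at all (y constant among used species)
        flat = ok & zero_res & (rss_red <= _RTOL_ZERO)
        F[flat] = 0.0
        return F, rss_full, rss_red

    def p_values(self, F: np.ndarray, with_habitat: bool) -> np.ndarray:
        dfn, dfd = self.dfs(with_habitat)
        p = np.full(self.m, np.nan)
        ok = self.tested_mask(with_habitat) & np.isfinite(F)
        p[ok] = sps.f.sf(F[ok], dfn[ok], dfd[ok])
        p[np.isinf(F)] = 0.0
        return p


def scan_alignment(
    aln: AlignmentMatrix,
    traits: pd.DataFrame,
    models: Sequence[str] = MODELS,
    low_complexity: bool = True,
    lc_ref_row: str | None = None,
    lc_params: dict | None = None,
) -> pd.DataFrame:
    """Fit the configured models to every alignment column.

    Returns one row per column per model with columns
    (column, model, F, p_value, df_num, df_den, n_used, n_classes, flags).
    Skipped columns (monomorphic, or zero estimable allele df) carry NaN
    F/p.  The low-complexity flag is advisory annotation only.
    """
    for mdl in models:
        if mdl not in MODELS:
            raise ValueError(f"unknown model {mdl!r}")
    eng = ScanEngine(aln, traits)
    lc_flags = np.zeros(aln.n_columns, dtype=bool)
    if low_complexity:
        ref = lc_ref_row if lc_ref_row is not None else aln.ids[0]
        lc_flags = flag_low_complexity_all(aln, ref_row=ref, **(lc_params or {}))

    frames = []
    for mdl in models:
        wh = mdl == "allele+habitat"
        n_col = aln.n_columns
        F_full = np.full(n_col, np.nan)
        p_full = np.full(n_col, np.nan)
        dfn_full = np.zeros(n_col, dtype=int)
        dfd_full = np.zeros(n_col, dtype=int)
        flags_full = [set() for _ in range(n_col)]
        if eng.m:
            F, _, _ = eng.stats(eng.y0, wh)
            p = eng.p_values(F, wh)
            dfn, dfd = eng.dfs(wh)
            tested = eng.tested_mask(wh)
            dfn_full[eng.cols] = dfn
            dfd_full[eng.cols] = dfd
            F_full[eng.cols[tested]] = F[tested]
            p_full[eng.cols[tested]] = p[tested]
            singleton = eng.singleton_all[eng.cols]
            collinear = dfn < 1
            zero_res = tested & np.isinf(F)
            for i, c in enumerate(eng.cols):
                fl = flags_full[c]
                if singleton[i]:
                    fl.add(FLAG_SINGLETON)
                if collinear[i]:
                    fl.add(FLAG_COLLINEAR)
                if zero_res[i]:
                    fl.add(FLAG_ZERO_RESIDUAL)
        for c in range(n_col):
            if eng.k_all[c] < 2:
                flags_full[c].add(FLAG_MONOMORPHIC)
            if lc_flags[c]:
                flags_full[c].add(FLAG_LOW_COMPLEXITY)
        frames.append(
            pd.DataFrame(
                {
                    "column": np.arange(1, n_col + 1),
                    "model": mdl,
                    "F": F_full,
                    "p_value": p_full,
                    "df_num": dfn_full,
                    "df_den": dfd_full,
                    "n_used": eng.n_used_all,
                    "n_classes": eng.k_all,
                    "flags": [",".join(sorted(f)) for f in flags_full],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fit_column_model(
    col: ColumnData, traits: pd.DataFrame, with_habitat: bool = False
) -> ColumnResult:
    """Fit one column's linear model (partial F-test of the allele factor)."""
    chars = np.array(
        [[a if a is not None else "-" for a in col.alleles]], dtype="U1"
    ).T.reshape(len(col.species), 1)
    aln = AlignmentMatrix(ids=list(col.species), chars=chars)
    mdl = "allele+habitat" if with_habitat else "allele"
    res = scan_alignment(aln, traits, models=(mdl,), low_complexity=False)
    row = res.iloc[0]
    flags = frozenset(row["flags"].split(",")) - {""}
    return ColumnResult(
        column=col.column,
        model=mdl,
        F=None if pd.isna(row["F"]) else float(row["F"]),
        p_value=None if pd.isna(row["p_value"]) else float(row["p_value"]),
        df_num=int(row["df_num"]),
        df_den=int(row["df_den"]),
        n_used=int(row["n_used"]),
        n_classes=int(row["n_classes"]),
        flags=flags,
    )


def permute_traits(
    traits: pd.DataFrame, stratified: bool = False, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Permute mass values across species; habitats and clades stay fixed.

    With ``stratified=True`` masses are shuffled independently within each
    habitat group, so each group keeps its own mass multiset.
    """
    rng = rng if rng is not None else np.random.default_rng()
    out = traits.copy()
    cols = [c for c in ("mass_kg", "log_mass") if c in out.columns]
    if stratified:
        for _, idx in out.groupby("habitat", observed=True).groups.items():
            perm = rng.permutation(len(idx))
            for c in cols:
                out.loc[idx, c] = out.loc[idx, c].to_numpy()[perm]
    else:
        perm = rng.permutation(len(out))
        for c in cols:
            out[c] = out[c].to_numpy()[perm]
    return out


def _permute_y(
    y: np.ndarray, h: np.ndarray, stratified: bool, rng: np.random.Generator
) -> np.ndarray:
    if not stratified:
        return y[rng.permutation(len(y))]
    out = y.copy()
    for val in (0.0, 1.0):
        idx = np.nonzero(h == val)[0]
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def permutation_hits(
    eng: ScanEngine,
    thresholds: Sequence[float],
    with_habitat: bool,
    n_perm: int,
    stratified: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hit counts (columns with p <= t) for ``n_perm`` permuted trait vectors.

    Returns an (n_perm, n_thresholds) integer array.  Hits are counted by
    comparing F against the per-column critical value at each threshold, which
    is equivalent to p <= t and avoids n_perm survival-function evaluations.
    """
    tested = eng.tested_mask(with_habitat)
    dfn, dfd = eng.dfs(with_habitat)
    t_idx = np.nonzero(tested)[0]
    thresholds = np.asarray(thresholds, dtype=float)
    # critical F per (threshold, tested column), cached over unique df pairs
    pairs = dfn[t_idx] * 100000 + dfd[t_idx]
    uniq, inv = np.unique(pairs, return_inverse=True)
    fcrit = np.empty((len(thresholds), len(uniq)))
    for j, pair in enumerate(uniq):
        fcrit[:, j] = sps.f.isf(thresholds, pair // 100000, pair % 100000)
    fcrit_cols = fcrit[:, inv]  # (n_t, n_tested)
    hits = np.zeros((n_perm, len(thresholds)), dtype=np.int64)
    for p in range(n_perm):
        yp = _permute_y(eng.y0, eng.h, stratified, rng)
        F, _, _ = eng.stats(yp, with_habitat)
        Ft = F[t_idx]
        hits[p] = (Ft[None, :] >= fcrit_cols).sum(axis=1)
    return hits


def estimate_fdr(
    aln: AlignmentMatrix,
    traits: pd.DataFrame,
    thresholds: Sequence[float],
    n_perm: int = 1000,
    n_runs: int = 2,
    stratified: bool = False,
    seed: int = 0,
    model: str = "allele",
) -> list[FdrEstimate]:
    """Permutation FDR estimates at each p-value threshold.

    For each threshold t: hits_original = tested columns with p <= t on the
    real traits; each of ``n_runs`` independent runs re-scans ``n_perm``
    permuted trait tables (identical tested-column set) and FDR = average
    permuted hits / original hits.  Runs are reported separately so their
    agreement can be used as a stability check.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    thresholds = list(thresholds)
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError(f"threshold {t} outside (0, 1)")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    wh = model == "allele+habitat"
    eng = ScanEngine(aln, traits)
    if eng.m == 0:
        raise ValidationError("no polymorphic columns to test")
    F0, _, _ = eng.stats(eng.y0, wh)
    p0 = eng.p_values(F0, wh)
    tested = eng.tested_mask(wh)
    hits0 = np.array(
        [int(((p0 <= t) & tested).sum()) for t in thresholds], dtype=np.int64
    )
    children = np.random.SeedSequence(seed).spawn(n_runs)
    run_hits = []  # (n_runs, n_perm, n_t)
    for r in range(n_runs):
        rng = np.random.default_rng(children[r])
        run_hits.append(
            permutation_hits(eng, thresholds, wh, n_perm, stratified, rng)
        )
    all_hits = np.stack(run_hits)
    out = []
    for j, t in enumerate(thresholds):
        per_run_mean = [float(all_hits[r, :, j].mean()) for r in range(n_runs)]
        per_run_fdr = [
            (m / hits0[j]) if hits0[j] > 0 else None for m in per_run_mean
        ]
        mean_all = float(all_hits[:, :, j].mean())
        out.append(
            FdrEstimate(
                threshold=t,
                hits_original=int(hits0[j]),
                mean_hits_permuted=mean_all,
                fdr=(mean_all / hits0[j]) if hits0[j] > 0 else None,
                n_permutations=n_perm,
                n_runs=n_runs,
                per_run_mean_hits=per_run_mean,
                per_run_fdr=per_run_fdr,
                stratified=stratified,
                model=model,
                seed=seed,
            )
        )
    return out


def fdr_table(estimates: Iterable[FdrEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {
            "model": e.model,
            "threshold": e.threshold,
            "hits_original": e.hits_original,
            "mean_hits_permuted": e.mean_hits_permuted,
            "fdr": e.fdr if e.fdr is not None else "undefined",
            "n_permutations": e.n_permutations,
            "n_runs": e.n_runs,
            "stratified": e.stratified,
            "seed": e.seed,
        }
        for r, f in enumerate(e.per_run_fdr, 1):
            row[f"fdr_run{r}"] = f if f is not None else "undefined"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# low-complexity / alignment-artifact flag
# ---------------------------------------------------------------------------

def _repeat_coverage(seq: str, max_unit: int = 2, min_units: int = 3) -> float:
    """Fraction of ``seq`` covered by tandem repeats of a 1- or 2-mer.

    A run counts when the unit repeats at least ``min_units`` times
    consecutively.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    covered = np.zeros(n, dtype=bool)
    for u in range(1, max_unit + 1):
        i = 0
        while i + u <= n:
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            run_len = j - i
            if run_len >= u * min_units:
                covered[i:j] = True
                i = j
            else:
                i += 1
    return float(covered.mean())


def flag_low_complexity(
    aln: AlignmentMatrix,
    column: int,
    ref_row: str | None = None,
    half_width: int = 10,
    gap_cutoff: float = 0.5,
    max_distinct: int = 2,
    repeat_cutoff: float = 0.8,
) -> bool:
    """Advisory flag for columns in gap-rich or low-complexity context.

    True when, in the +-``half_width`` column window around ``column``, the
    overall gap fraction exceeds ``gap_cutoff``, or the reference row's
    (ungapped) subsequence has <= ``max_distinct`` distinct bases, or tandem
    mono-/di-nucleotide repeats cover more than ``repeat_cutoff`` of it.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    ref = ref_row if ref_row is not None else aln.ids[0]
    lo = max(0, column - 1 - half_width)
    hi = min(aln.n_columns, column + half_width)
    window = aln.chars[:, lo:hi]
    if (window == "-").mean() > gap_cutoff:
        return True
    sub = "".join(c for c in aln.row(ref)[lo:hi] if c != "-")
    if not sub:
        return True
    if len(set(sub)) <= max_distinct:
        return True
    return _repeat_coverage(sub) > repeat_cutoff


def flag_low_complexity_all(
    aln: AlignmentMatrix,
    ref_row: str | None = None,
    half_width: int = 10,
    gap_cutoff: float = 0.5,
    max_distinct: int = 2,
    repeat_cutoff: float = 0.8,
) -> np.ndarray:
    """Vector of low-complexity flags for every column (1..n_columns)."""
    ref = ref_row if ref_row is not None else aln.ids[0]
    n = aln.n_columns
    gaps = aln.chars == "-"
    # sliding-window gap fraction via cumulative sums
    csum = np.concatenate([[0], gaps.sum(axis=0).cumsum()])
    out = np.zeros(n, dtype=bool)
    ref_chars = aln.row(ref)
    for c in range(1, n + 1):
        lo = max(0, c - 1 - half_width)
        hi = min(n, c + half_width)
        gap_frac = (csum[hi] - csum[lo]) / (aln.n_species * (hi - lo))
        if gap_frac > gap_cutoff:
            out[c - 1] = True
            continue
        sub = "".join(ch for ch in ref_chars[lo:hi] if ch != "-")
        if not sub or len(set(sub)) <= max_distinct:
            out[c - 1] = True
            continue
        if _repeat_coverage(sub) > repeat_cutoff:
            out[c - 1] = True
    return out
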