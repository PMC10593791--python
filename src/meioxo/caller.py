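"""Crossover calling from sparse allele-count marker tables.

The caller mirrors a GBS workflow: discard whole libraries with too few
reads, discard low-quality / low-coverage marker sites, call a three-state
genotype (AA/AB/BB) per site from the allele fractions, denoise with a
sliding-window majority vote, segment into maximal genotype runs, and call
one crossover per genotype switch, placed at the midpoint between the two
flanking informative markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerTable",
    "FilterConfig",
    "FilterReport",
    "filter_markers",
    "call_genotypes",
    "segment_track",
    "call_crossovers",
    "count_per_individual",
]

MARKER_COLUMNS = ["individual", "chrom", "pos", "ref_count", "alt_count", "quality"]


@dataclass
class MarkerTable:
    """Per-individual allele counts at shared SNP sites.

    ``df`` columns: individual, chrom, pos (1-based), ref_count, alt_count,
    quality.  ``library_reads`` gives each individual's total sequencing-read
    count (genome-wide, not just at SNPs), used by the library-size filter.
    """

    df: pd.DataFrame
    library_reads: pd.Series

    def __post_init__(self):
        missing = [c for c in MARKER_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"marker table missing columns {missing}")
        if (self.df[["ref_count", "alt_count"]] < 0).any().any():
            raise ValueError("allele counts must be non-negative")

    @property
    def individuals(self):
        return list(self.library_reads.index)


@dataclass(frozen=True)
class FilterConfig:
    """Marker/library filters; all comparisons use the boundary semantics below.

    Sites are kept only with mapping quality strictly > ``min_site_quality``
    (quality is a property of the site, shared across libraries); a marker
    row is kept only if its read depth in that library is strictly
    > ``min_mean_coverage``; libraries with strictly fewer than
    ``min_library_reads`` total reads are discarded (a library at exactly
    the threshold is kept).
    """

    min_site_quality: float = 100.0
    min_mean_coverage: float = 2.5
    min_library_reads: int = 100_000

    def __post_init__(self):
        if min(self.min_site_quality, self.min_mean_coverage, self.min_library_reads) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterReport:
    individuals_in: int = 0
    individuals_dropped: int = 0
    rows_in: int = 0
    rows_dropped_quality: int = 0
    rows_dropped_coverage: int = 0
    rows_out: int = 0
    empty_output: bool = False

    def as_dict(self):
        return dict(self.__dict__)


def filter_markers(table: MarkerTable, cfg: FilterConfig = FilterConfig()):
    """Apply library-size, site-quality and coverage filters.

    Quality and coverage are row-level predicates (a site's quality is shared
    by every library; depth is each library's own), so the site filters and
    the library filter commute and can be applied in either order.
    Returns ``(filtered_table, FilterReport)``.
    """
    report = FilterReport(individuals_in=len(table.library_reads))
    keep_ind = table.library_reads[table.library_reads >= cfg.min_library_reads]
    report.individuals_dropped = report.individuals_in - len(keep_ind)
    df = table.df[table.df["individual"].isin(keep_ind.index)]
    report.rows_in = len(df)

    bad_quality = df["quality"] <= cfg.min_site_quality
    depth = df["ref_count"] + df["alt_count"]
    bad_coverage = depth <= cfg.min_mean_coverage
    report.rows_dropped_quality = int(bad_quality.sum())
    report.rows_dropped_coverage = int((bad_coverage & ~bad_quality).sum())

    out = df[~(bad_quality | bad_coverage)].reset_index(drop=True)
    report.rows_out = len(out)
    report.empty_output = len(out) == 0
    return MarkerTable(out, keep_ind), report


# --- genotype calling -----------------------------------------------------

GENOTYPE_STATES = ("AA", "AB", "BB")


def call_genotypes(
    table: MarkerTable,
    hom_fraction: float = 0.1,
    het_band: tuple = (0.3, 0.7),
    hom_error: float = 0.05,
    max_site_evidence: float = 4.0,
) -> pd.DataFrame:
    """Per-site three-state genotype calls from allele fractions.

    A site is AA if its alt fraction is <= ``hom_fraction``, BB if
    >= 1 - ``hom_fraction``, AB if inside ``het_band``, otherwise missing
    (as is any zero-depth site).  The score is the log10 binomial likelihood
    ratio of the best versus second-best state, with homozygous states
    modelled as Binomial(depth, ``hom_error``) / Binomial(depth, 0.5) /
    Binomial(depth, 1 - ``hom_error``).

    The output also carries the per-state relative log-likelihoods
    (``ll_AA``/``ll_AB``/``ll_BB``, natural log, 0 for the best state) used
    by the likelihood-vote segmenter; each site's evidence is capped at
    ``max_site_evidence`` so no single deep site can outvote a window.
    """
    df = table.df
    depth = (df["ref_count"] + df["alt_count"]).to_numpy()
    alt = df["alt_count"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)

    call = np.full(len(df), "missing", dtype=object)
    call[frac <= hom_fraction] = "AA"
    call[frac >= 1.0 - hom_fraction] = "BB"
    call[(frac >= het_band[0]) & (frac <= het_band[1])] = "AB"
    call[depth == 0] = "missing"

    logpmf = np.stack(
        [stats.binom.logpmf(alt, depth, p) for p in (hom_error, 0.5, 1.0 - hom_error)]
    )
    order = np.sort(logpmf, axis=0)
    score = np.where(depth > 0, (order[-1] - order[-2]) / np.log(10.0), 0.0)
    rel = logpmf - logpmf.max(axis=0)
    rel = np.maximum(rel, -max_site_evidence)
    rel[:, depth == 0] = 0.0

    out = df[["individual", "chrom", "pos"]].copy()
    out["depth"] = depth
    out["call"] = call
    out["score"] = score
    out["ll_AA"] = rel[0]
    out["ll_AB"] = rel[1]
    out["ll_BB"] = rel[2]
    return out


# --- segmentation ---------------------------------------------------------


def _windowed_states(evidence: np.ndarray, k: int) -> np.ndarray:
    """Per-site state (0/1/2) maximising summed evidence over a k-site window.

    With one-hot evidence this is the plain majority vote (ties resolved to
    the lowest state code, deterministically); with log-likelihood evidence
    it is a windowed maximum-likelihood vote.
    """
    n = evidence.shape[0]
    half = k // 2
    cum = np.vstack([np.zeros(3), np.cumsum(evidence, axis=0)])
    idx = np.arange(n)
    win = cum[np.minimum(n, idx + half + 1)] - cum[np.maximum(0, idx - half)]
    return np.argmax(win, axis=1)


def _refine_boundary(evidence: np.ndarray, b: int, lo: int, hi: int, sl: int, sr: int) -> int:
    """Exact changepoint between states sl (left) and sr (right) near index b.

    Windowed voting places the switch where the window majority flips, which
    can sit a few sites off when the two states carry asymmetric per-site
    evidence; this picks the split j in [lo, hi] maximising
    sum(evidence[:j, sl]) + sum(evidence[j:, sr]) over the local stretch.
    """
    gain = evidence[lo:hi, sl] - evidence[lo:hi, sr]
    # prefix[j] = evidence of splitting after lo + j
    prefix = np.concatenate([[0.0], np.cumsum(gain)])
    best = int(np.argmax(prefix))
    # among ties pick the split closest to the smoothed boundary
    ties = np.flatnonzero(prefix == prefix[best])
    best = int(ties[np.argmin(np.abs(ties - (b - lo)))])
    return lo + best


def _merge_short_runs(states, lengths, m):
    """Merge runs shorter than m sites into a flanking run (larger, tie: left)."""
    states, lengths = list(states), list(lengths)
    changed = True
    while changed and len(states) > 1:
        changed = False
        i = int(np.argmin(lengths))
        if lengths[i] < m:
            if i == 0:
                j = 1
            elif i == len(states) - 1:
                j = i - 1
            else:
                j = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
            lengths[j] += lengths[i]
            del states[i], lengths[i]
            # re-merge adjacent equal states
            k = 0
            while k < len(states) - 1:
                if states[k] == states[k + 1]:
                    lengths[k] += lengths[k + 1]
                    del states[k + 1], lengths[k + 1]
                else:
                    k += 1
            changed = True
    return states, lengths


def segment_track(
    genotypes: pd.DataFrame,
    smoothing_window: int = 5,
    min_support: int = 3,
    mode: str = "likelihood",
) -> pd.DataFrame:
    """Smooth genotype calls and emit maximal genotype runs per chromosome.

    ``mode="majority"`` is the plain per-site majority vote over a
    ``smoothing_window``-site sliding window (missing calls excluded);
    ``mode="likelihood"`` (default) replaces counted votes with each site's
    capped per-state log-likelihoods, which keeps low-depth sites — where a
    single read makes a heterozygous site look homozygous — from outvoting
    their neighbourhood.  Runs supported by fewer than ``min_support`` sites
    are merged into the flanking state, and each surviving run boundary is
    refined to the exact changepoint that maximises the flanking states'
    evidence.  Chromosomes with fewer than ``min_support`` informative sites
    yield no segments and are listed in the result's ``skipped`` attribute.
    """
    if smoothing_window % 2 != 1:
        raise ValueError("smoothing window must be odd")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if mode not in ("likelihood", "majority"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    has_ll = all(c in genotypes.columns for c in ("ll_AA", "ll_AB", "ll_BB", "depth"))
    if mode == "likelihood" and not has_ll:
        raise ValueError("likelihood mode needs the ll_* columns from call_genotypes")
    segments = []
    skipped = []
    for (ind, chrom), grp in genotypes.groupby(["individual", "chrom"], sort=True):
        grp = grp.sort_values("pos", kind="stable")
        if mode == "likelihood":
            grp = grp[grp["depth"] > 0]
            evidence = grp[["ll_AA", "ll_AB", "ll_BB"]].to_numpy()
        else:
            grp = grp[grp["call"] != "missing"]
            codes = np.array([GENOTYPE_STATES.index(c) for c in grp["call"]])
            evidence = np.zeros((codes.size, 3))
            if codes.size:
                evidence[np.arange(codes.size), codes] = 1.0
        if len(grp) < min_support:
            skipped.append((ind, chrom))
            continue
        pos = grp["pos"].to_numpy()
        states = _windowed_states(evidence, smoothing_window)
        change = np.flatnonzero(states[1:] != states[:-1]) + 1
        starts = np.concatenate([[0], change])
        run_states = list(states[starts])
        run_lengths = list(np.diff(np.concatenate([starts, [states.size]])))
        run_states, run_lengths = _merge_short_runs(run_states, run_lengths, min_support)
        bounds = list(np.concatenate([[0], np.cumsum(run_lengths)]).astype(int))
        # refine each boundary within the two flanking runs
        for j in range(1, len(run_states)):
            bounds[j] = _refine_boundary(
                evidence, bounds[j], bounds[j - 1], bounds[j + 1],
                run_states[j - 1], run_states[j],
            )
        runs = [
            (state, lo, hi)
            for state, lo, hi in zip(run_states, bounds[:-1], bounds[1:])
            if hi > lo  # refinement may collapse a run entirely
        ]
        merged = []
        for state, lo, hi in runs:  # re-join same-state neighbours left by a collapse
            if merged and merged[-1][0] == state:
                merged[-1] = (state, merged[-1][1], hi)
            else:
                merged.append((state, lo, hi))
        for state, lo, hi in merged:
            segments.append(
                {
                    "individual": ind,
                    "chrom": chrom,
                    "state": GENOTYPE_STATES[int(state)],
                    "first_pos": int(pos[lo]),
                    "last_pos": int(pos[hi - 1]),
                    "n_sites": int(hi - lo),
                }
            )
    out = pd.DataFrame(
        segments,
        columns=["individual", "chrom", "state", "first_pos", "last_pos", "n_sites"],
    )
    out.attrs["skipped"] = skipped
    return out


def call_crossovers(segments: pd.DataFrame) -> pd.DataFrame:
    """One crossover call per adjacent segment pair.

    The flanking markers are the last informative site of the left segment
    and the first of the right; the midpoint is the floor of their mean.
    Direct AA->BB (or BB->AA) switches are genetically possible in an F2 only
    via a double crossover between adjacent markers and are flagged
    ``suspect`` for QC.
    """
    calls = []
    for (ind, chrom), grp in segments.groupby(["individual", "chrom"], sort=True):
        grp = grp.sort_values("first_pos", kind="stable").reset_index(drop=True)
        for i in range(len(grp) - 1):
            left, right = grp.loc[i], grp.loc[i + 1]
            lp, rp = int(left["last_pos"]), int(right["first_pos"])
            calls.append(
                {
                    "individual": ind,
                    "chrom": chrom,
                    "left_pos": lp,
                    "right_pos": rp,
                    "midpoint": (lp + rp) // 2,
                    "transition": f"{left['state']}->{right['state']}",
                    "suspect": {left["state"], right["state"]} == {"AA", "BB"},
                }
            )
    return pd.DataFrame(
        calls,
        columns=["individual", "chrom", "left_pos", "right_pos", "midpoint", "transition", "suspect"],
    )


def count_per_individual(calls: pd.DataFrame, individuals=None) -> pd.DataFrame:
    """Crossover calls per individual; individuals with zero calls appear as 0."""
    counts = calls.groupby("individual").size() if len(calls) else pd.Series(dtype=int)
    if individuals is not None:
        counts = counts.reindex(list(individuals), fill_value=0)
    return counts.rename("n_crossovers").astype(int).rename_axis("individual").reset_index()
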