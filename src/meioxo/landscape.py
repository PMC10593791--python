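"""Windowed crossover-landscape summaries and SNP-density-binned comparisons.

Crossover calls are binned into fixed-width windows (counts normalised per F2
individual), projected onto proportionally scaled telomere-to-centromere
chromosome arms, and — for the polymorphism analysis — 100-kb windows are
ranked by SNP density, grouped into equal-size runs, and per-group crossover
frequencies of two populations are differenced (delta-cM curves, with a
tricube local-quadratic trend line).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "make_windows",
    "bin_crossovers",
    "scaled_arm_profile",
    "profile_correlation",
    "snp_density_grouping",
    "group_recombination",
    "delta_cm",
    "loess_trend",
    "correlate_delta_density",
]


def make_windows(chrom_lengths: dict, window_bp: int, drop_partial: bool = False) -> pd.DataFrame:
    """Half-open fixed-width windows tiling each chromosome from 0.

    The last, shorter window is retained by default (its density statistics
    are normalised by its true length); ``drop_partial`` discards it.
    """
    if window_bp <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window_bp)
        for s in starts:
            e = min(s + window_bp, length)
            if e - s < window_bp and drop_partial:
                continue
            rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_crossovers(
    calls: pd.DataFrame,
    chrom_lengths: dict,
    window_bp: int,
    n_individuals: int,
    snp_positions: pd.DataFrame | None = None,
    drop_partial: bool = False,
) -> pd.DataFrame:
    """Assign crossover midpoints to half-open windows; normalise per F2.

    ``calls`` needs columns chrom, midpoint.  Optional ``snp_positions``
    (columns chrom, pos; 1-based) adds per-window SNP counts and SNPs/kb.
    Returns a window table with xo_count, xo_per_f2 and (if provided)
    snps_per_kb columns.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    windows = make_windows(chrom_lengths, window_bp, drop_partial)
    windows["xo_count"] = 0
    for chrom, grp in calls.groupby("chrom"):
        length = chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"calls on unknown chromosome {chrom!r}")
        mids = grp["midpoint"].to_numpy()
        if np.any((mids < 0) | (mids >= length)):
            raise ValueError(f"crossover midpoint outside chromosome {chrom!r}")
        mask = windows["chrom"] == chrom
        idx = mids // window_bp
        counts = np.bincount(idx.astype(int), minlength=int(mask.sum()))
        windows.loc[mask, "xo_count"] = counts[: int(mask.sum())]
    windows["xo_per_f2"] = windows["xo_count"] / n_individuals
    if snp_positions is not None:
        windows["snp_count"] = 0
        for chrom, grp in snp_positions.groupby("chrom"):
            mask = windows["chrom"] == chrom
            idx = ((grp["pos"].to_numpy() - 1) // window_bp).astype(int)
            idx = idx[idx < int(mask.sum())]
            windows.loc[mask, "snp_count"] = np.bincount(idx, minlength=int(mask.sum()))[
                : int(mask.sum())
            ]
        windows["snps_per_kb"] = windows["snp_count"] / ((windows["end"] - windows["start"]) / 1000.0)
    return windows


def scaled_arm_profile(
    calls: pd.DataFrame,
    chrom_lengths: dict,
    centromeres: dict,
    n_bins: int = 50,
    n_individuals: int = 1,
) -> pd.DataFrame:
    """Crossovers along proportionally scaled arms, telomere (0) to centromere (1).

    Each arm is mapped linearly onto [0, 1]; calls are binned by fractional
    position, aggregated over all arms, and normalised per F2 individual.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    fractions = []
    for chrom, grp in calls.groupby("chrom"):
        length, cen = chrom_lengths[chrom], centromeres[chrom]
        mids = grp["midpoint"].to_numpy(dtype=float)
        left = mids < cen
        frac = np.where(left, mids / cen, (length - mids) / (length - cen))
        fractions.append(frac)
    frac = np.concatenate(fractions) if fractions else np.empty(0)
    idx = np.clip((frac * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "tel_cen_fraction": (np.arange(n_bins) + 0.5) / n_bins,
            "xo_count": counts,
            "xo_per_f2": counts / n_individuals,
        }
    )


def profile_correlation(tracks: dict, method: str = "spearman") -> pd.DataFrame:
    """Pairwise correlation of windowed crossover profiles across populations.

    All tracks must share an identical (chrom, start, end) window grid.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least two tracks")
    grids = [t[["chrom", "start", "end"]].reset_index(drop=True) for t in tracks.values()]
    for g in grids[1:]:
        if not g.equals(grids[0]):
            raise ValueError("window grids differ between tracks")
    data = pd.DataFrame({k: t["xo_per_f2"].to_numpy() for k, t in tracks.items()})
    return data.corr(method=method)


def snp_density_grouping(windows: pd.DataFrame, group_size: int = 12):
    """Rank windows by SNP density and partition into equal-size groups.

    Windows are sorted ascending by (snps_per_kb, chrom, start) — the
    secondary keys make tied densities deterministic — and consecutive runs
    of ``group_size`` form groups 1..G with G = floor(n / group_size).  The
    trailing remainder (the highest-density ``n mod group_size`` windows) is
    excluded and returned separately.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = len(windows)
    if n < group_size:
        raise ValueError(f"{n} windows cannot form a group of {group_size}")
    ranked = windows.sort_values(
        ["snps_per_kb", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)
    n_groups = n // group_size
    grouped = ranked.iloc[: n_groups * group_size].copy()
    grouped["group"] = np.repeat(np.arange(1, n_groups + 1), group_size)
    excluded = ranked.iloc[n_groups * group_size :].copy()
    return grouped, excluded


def group_recombination(
    grouped: pd.DataFrame, calls: pd.DataFrame, n_individuals: int, window_bp: int = 100_000
) -> pd.DataFrame:
    """Per-group crossover frequency (cM per window) for one population.

    Each member window's crossover count is normalised to gametes sampled
    (2 per F2 individual) and expressed in cM (x100); the group value is the
    mean over its member windows, reported with the group's mean SNP density.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    counts = np.zeros(len(grouped))
    by_chrom = {c: g["midpoint"].to_numpy() for c, g in calls.groupby("chrom")}
    for i, row in enumerate(grouped.itertuples(index=False)):
        mids = by_chrom.get(row.chrom)
        if mids is None:
            continue
        counts[i] = np.count_nonzero((mids >= row.start) & (mids < row.end))
    g = grouped.copy()
    g["cm_per_window"] = 100.0 * counts / (2.0 * n_individuals)
    out = g.groupby("group").agg(
        mean_density=("snps_per_kb", "mean"), cm=("cm_per_window", "mean")
    )
    return out.reset_index()


def delta_cm(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.DataFrame:
    """Per-group cM difference a - b on identical group definitions."""
    if len(group_a) != len(group_b) or not np.array_equal(
        group_a["group"].to_numpy(), group_b["group"].to_numpy()
    ):
        raise ValueError("group definitions differ")
    if not np.allclose(group_a["mean_density"], group_b["mean_density"]):
        raise ValueError("group densities differ: groups built on different windows")
    out = group_a[["group", "mean_density"]].copy()
    out["delta_cm"] = group_a["cm"].to_numpy() - group_b["cm"].to_numpy()
    return out


def loess_trend(x, y, span: float = 0.75, degree: int = 2):
    """Local polynomial regression with tricube weights, evaluated at ``x``.

    For each point, the ``ceil(span * n)`` nearest neighbours are fit with a
    weighted degree-``degree`` polynomial.  A constant y reproduces the
    constant and, with degree >= 1 and span = 1, a straight line is
    reproduced to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    q = int(np.ceil(span * n))
    if q < degree + 1:
        raise ValueError("span too small for the polynomial degree")
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(q)
        w = np.clip(w, 1e-12, None)
        deg = min(degree, len(np.unique(x[idx])) - 1)
        coeffs = np.polyfit(x[idx] - x[i], y[idx], deg, w=np.sqrt(w))
        fitted[i] = coeffs[-1]
    return fitted


def correlate_delta_density(x, y, method: str = "spearman"):
    """Rank (or linear) correlation between SNP density and delta-cM.

    Returns ``(rho, p_value, n)`` with a two-sided P from the standard
    backend; constant input is flagged as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), int(x.size)
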