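"""Fluorescent-tagged-line (FTL) genetic-distance and interference estimators.

Seed system: an F1 hemizygous for two linked seed-expressed fluorophores
(eGFP, dsRed) in coupling phase is selfed; the fraction of single-colour
seeds among all seeds is an invertible function of the recombination
fraction between the transgenes.  Pollen system: hemizygous fluorophores in
pollen allow direct gamete counting by flow cytometry — two-colour counts
give one interval's genetic distance, three-colour (eight-class) counts give
two adjacent distances plus the coefficient of coincidence (CoC), hence
interference = 1 - CoC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeedCountSet",
    "PollenClassCounts",
    "IntervalEstimate",
    "InterferenceEstimate",
    "SeedIntensityTable",
    "classify_seeds",
    "suggest_valley_threshold",
    "seed_cm",
    "pollen_cm_two_color",
    "i3bc_interference",
    "compare_groups",
]


@dataclass(frozen=True)
class SeedCountSet:
    """Seed fluorescence class tallies."""

    n_green_only: int
    n_red_only: int
    n_both: int
    n_neither: int

    def __post_init__(self):
        if min(self.n_green_only, self.n_red_only, self.n_both, self.n_neither) < 0:
            raise ValueError("seed counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_green_only + self.n_red_only + self.n_both + self.n_neither


# 8-class keys: which of the three ordered fluorophore markers (m1, m2, m3,
# ordered by genomic position) a pollen grain carries.
EIGHT_CLASS_KEYS = frozenset(
    {"".join(s) if s else "none" for k in range(4) for s in itertools.combinations(("m1", "m2", "m3"), k)}
)
FOUR_CLASS_KEYS = frozenset({"R", "Y", "RY", "N"})


@dataclass(frozen=True)
class PollenClassCounts:
    """Pollen flow-cytometry class counts, 4-class (R/Y/RY/N) or 8-class."""

    counts: dict

    def __post_init__(self):
        keys = set(self.counts)
        if keys != EIGHT_CLASS_KEYS and keys != FOUR_CLASS_KEYS:
            raise ValueError(f"class keys must be the 4- or 8-class set, got {sorted(keys)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be non-negative")

    @property
    def is_eight_class(self) -> bool:
        return set(self.counts) == EIGHT_CLASS_KEYS

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class IntervalEstimate:
    cM: float
    n_total: int
    standard_error: float


@dataclass(frozen=True)
class InterferenceEstimate:
    d_b: float
    d_c: float
    observed_dco: int
    expected_dco: float
    coc: float
    interference: float
    n_total: int


@dataclass(frozen=True)
class SeedIntensityTable:
    """Per-seed two-channel fluorescence intensities plus manual thresholds."""

    table: pd.DataFrame  # columns: seed_id, red, green
    red_threshold: float
    green_threshold: float

    def __post_init__(self):
        for col in ("red", "green"):
            if col not in self.table.columns:
                raise ValueError(f"intensity table missing column {col!r}")
            if (self.table[col] < 0).any():
                raise ValueError("intensities must be non-negative")
        if self.red_threshold <= 0 or self.green_threshold <= 0:
            raise ValueError("thresholds must be positive")


def classify_seeds(table: SeedIntensityTable) -> SeedCountSet:
    """Threshold two-channel intensities into the four seed classes.

    Thresholds are user-supplied (set manually from the fluorescence
    histograms); a seed is positive for a channel iff its intensity strictly
    exceeds that channel's threshold.
    """
    if len(table.table) == 0:
        raise ValueError("empty seed intensity table")
    green = table.table["green"].to_numpy() > table.green_threshold
    red = table.table["red"].to_numpy() > table.red_threshold
    return SeedCountSet(
        n_green_only=int(np.sum(green & ~red)),
        n_red_only=int(np.sum(red & ~green)),
        n_both=int(np.sum(green & red)),
        n_neither=int(np.sum(~green & ~red)),
    )


def suggest_valley_threshold(intensities, bins: int = 100) -> float:
    """Optional helper: histogram-valley threshold between two intensity modes.

    Never applied automatically — classification always uses the thresholds
    supplied in :class:`SeedIntensityTable`.
    """
    x = np.log1p(np.asarray(intensities, dtype=float))
    hist, edges = np.histogram(x, bins=bins)
    peaks = [i for i in range(1, bins - 1) if hist[i] >= hist[i - 1] and hist[i] >= hist[i + 1]]
    if len(peaks) < 2:
        raise ValueError("no bimodal structure found; set the threshold manually")
    lo, hi = peaks[0], peaks[-1]
    valley = lo + int(np.argmin(hist[lo : hi + 1]))
    return float(np.expm1(0.5 * (edges[valley] + edges[valley + 1])))


def seed_cm(counts: SeedCountSet) -> IntervalEstimate:
    """Genetic distance from seed fluorescence class counts.

    With f = (NG + NR)/NT the single-colour fraction, the selfing algebra
    gives f = (1 - q^2)/2 for q = 1 - r, hence

        cM = 100 * (1 - sqrt(1 - 2 f)).

    The standard error comes from delta-method propagation of the binomial
    variance of f: SE = 100 * sqrt(f (1 - f) / NT) / sqrt(1 - 2 f).
    """
    nt = counts.n_total
    if nt <= 0:
        raise ValueError("n_total must be positive")
    f = (counts.n_green_only + counts.n_red_only) / nt
    if f > 0.5:
        raise ValueError(
            f"single-colour fraction {f:.3f} > 0.5 is outside the estimator's feasible "
            "domain (would imply recombination fraction > 1)"
        )
    cm = 100.0 * (1.0 - math.sqrt(1.0 - 2.0 * f))
    se = 100.0 * math.sqrt(f * (1.0 - f) / nt) / math.sqrt(1.0 - 2.0 * f) if f < 0.5 else float("inf")
    return IntervalEstimate(cM=cm, n_total=nt, standard_error=se)


def pollen_cm_two_color(counts: PollenClassCounts) -> IntervalEstimate:
    """Genetic distance from 4-class pollen counts: cM = 100 * Y / (Y + RY)."""
    if counts.is_eight_class:
        raise ValueError("two-colour estimator needs 4-class (R/Y/RY/N) counts")
    y, ry = counts.counts["Y"], counts.counts["RY"]
    if y + ry == 0:
        raise ValueError("Y + RY = 0: estimate undefined")
    frac = y / (y + ry)
    se = 100.0 * math.sqrt(frac * (1.0 - frac) / (y + ry))
    return IntervalEstimate(cM=100.0 * frac, n_total=counts.n_total, standard_error=se)


# class membership for the three-marker (I3bc-style) layout
_DCO_CLASSES = ("m1m3", "m2")
_SINGLE_B_CLASSES = ("m1", "m2m3")
_SINGLE_C_CLASSES = ("m1m2", "m3")


def i3bc_interference(counts: PollenClassCounts) -> InterferenceEstimate:
    """Two-interval genetic distances, CoC and interference from 8-class counts.

    Recombinants in interval b (m1-m2) are the single-b classes plus both
    double-crossover classes; likewise for interval c (m2-m3).  Genetic
    distances divide recombinant totals by all pollen grains; the expected
    DCO count under independence is (d_b/100)(d_c/100) * n_total, and
    CoC = observed / expected, interference = 1 - CoC.
    """
    if not counts.is_eight_class:
        raise ValueError("interference estimator needs 8-class counts")
    c = counts.counts
    n = counts.n_total
    if n <= 0:
        raise ValueError("n_total must be positive")
    observed_dco = sum(c[k] for k in _DCO_CLASSES)
    rec_b = sum(c[k] for k in _SINGLE_B_CLASSES) + observed_dco
    rec_c = sum(c[k] for k in _SINGLE_C_CLASSES) + observed_dco
    d_b = 100.0 * rec_b / n
    d_c = 100.0 * rec_c / n
    expected_dco = (d_b / 100.0) * (d_c / 100.0) * n
    if expected_dco == 0:
        raise ValueError("expected DCO count is 0: interference undefined")
    coc = observed_dco / expected_dco
    return InterferenceEstimate(
        d_b=d_b,
        d_c=d_c,
        observed_dco=observed_dco,
        expected_dco=expected_dco,
        coc=coc,
        interference=1.0 - coc,
        n_total=n,
    )


def compare_groups(groups: dict, test: str = "welch", alpha: float = 0.05) -> pd.DataFrame:
    """Compare per-line replicate measurements with a named standard test.

    ``test`` is one of ``"welch"`` (pairwise Welch's t), ``"kruskal"``
    (Kruskal-Wallis H followed by pairwise Mann-Whitney U with Bonferroni
    correction) or ``"anova_tukey"`` (one-way ANOVA with Tukey HSD).  All
    statistics are delegated to scipy / statsmodels; the report records the
    test name, statistic, two-sided P and any multiplicity correction.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two replicates")
    pairs = list(itertools.combinations(names, 2))
    rows = []
    if test == "welch":
        for a, b in pairs:
            res = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
            rows.append(
                {"test": "welch_t", "group_a": a, "group_b": b,
                 "statistic": res.statistic, "p_value": res.pvalue,
                 "correction": "none", "adjusted_alpha": alpha}
            )
    elif test == "kruskal":
        h = stats.kruskal(*arrays.values())
        rows.append(
            {"test": "kruskal_wallis", "group_a": "all", "group_b": "all",
             "statistic": h.statistic, "p_value": h.pvalue,
             "correction": "none", "adjusted_alpha": alpha}
        )
        adj = alpha / len(pairs)
        for a, b in pairs:
            res = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
            rows.append(
                {"test": "mann_whitney_u", "group_a": a, "group_b": b,
                 "statistic": res.statistic, "p_value": res.pvalue,
                 "correction": "bonferroni", "adjusted_alpha": adj}
            )
    elif test == "anova_tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        f = stats.f_oneway(*arrays.values())
        rows.append(
            {"test": "one_way_anova", "group_a": "all", "group_b": "all",
             "statistic": f.statistic, "p_value": f.pvalue,
             "correction": "none", "adjusted_alpha": alpha}
        )
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[k] * arrays[k].size for k in names])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        for (a, b), stat, p in zip(
            itertools.combinations(tk.groupsunique, 2), tk.meandiffs, tk.pvalues
        ):
            rows.append(
                {"test": "tukey_hsd", "group_a": a, "group_b": b,
                 "statistic": stat, "p_value": p,
                 "correction": "tukey", "adjusted_alpha": alpha}
            )
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
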