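"""Synthetic meiosis: F2 populations, GBS-like marker tables, seed and pollen counts.

Class I (interfering) crossovers are drawn from a stationary gamma-renewal
("counting") process on the genetic scale of the bivalent, with shape ``nu``
(``nu = 1`` is the Poisson, no-interference limit) and each event retained
with probability 1/2 (two of four chromatids are involved in any crossover).
Class II crossovers are an independent inhomogeneous Poisson process, thinned
likewise.  Every simulated event is recorded as ground truth, whether or not
downstream genotyping could detect it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import MarkerTable
from .ftl import PollenClassCounts, SeedCountSet
from .genome import GenomeModel, PathwayParams, PiecewiseTrack

__all__ = [
    "IntensityProfiles",
    "Gamete",
    "F2Individual",
    "build_intensity_profiles",
    "simulate_gamete",
    "simulate_f2_population",
    "truth_calls",
    "simulate_gbs",
    "seed_class_probabilities",
    "simulate_seed_counts",
    "pollen_class_probabilities",
    "simulate_pollen_counts",
    "coc_from_gametes",
]

_MAX_OBLIGATE_REDRAWS = 10_000


@dataclass(frozen=True)
class IntensityProfiles:
    """Per-chromosome Class I / Class II crossover intensity tracks (cM/Mb)."""

    classI: dict
    classII: dict
    nu: float
    obligate_CO: bool

    def total_cM(self, chrom: str) -> tuple:
        return (_track_cM(self.classI[chrom]), _track_cM(self.classII[chrom]))


def _track_cM(track: PiecewiseTrack) -> float:
    # values are cM/Mb, edges bp
    return float(np.sum(track.values * np.diff(track.edges)) / 1e6)


def build_intensity_profiles(
    model: GenomeModel, params: PathwayParams, step_bp: int = 10_000
) -> IntensityProfiles:
    """Evaluate pathway intensities along each chromosome.

    Intensity is defined genome-wide: crossovers form in homozygous blocks
    too, they are just undetectable there (no informative markers).  The
    polymorphism-response multipliers are evaluated at segment midpoints of a
    ``step_bp`` grid refined with the SNP-density-track and het-block edges.
    """
    params.validate()
    classI, classII = {}, {}
    for name, length in model.chromosomes:
        density = model.snp_density[name]
        edges = np.unique(
            np.concatenate(
                [
                    np.arange(0.0, length, step_bp),
                    [float(length)],
                    density.edges,
                    np.array(
                        [b for blk in model.het_blocks.get(name, []) for b in blk],
                        dtype=float,
                    ),
                ]
            )
        )
        edges = edges[(edges >= 0) & (edges <= length)]
        mids = 0.5 * (edges[:-1] + edges[1:])
        dens = density.value_at(mids)
        vI = np.empty(mids.size)
        vII = np.empty(mids.size)
        for i, (x, d) in enumerate(zip(mids, dens)):
            if model.is_het(name, x):
                bdist = model.boundary_distance(name, x)
                vI[i] = params.classI_base_cM_per_Mb * params.classI_multiplier(d, bdist)
            else:
                vI[i] = params.classI_base_cM_per_Mb
            vII[i] = params.classII_base_cM_per_Mb * params.classII_multiplier(d)
        classI[name] = PiecewiseTrack(edges, vI)
        classII[name] = PiecewiseTrack(edges, vII)
    return IntensityProfiles(
        classI=classI,
        classII=classII,
        nu=params.classI_interference_shape,
        obligate_CO=params.obligate_CO,
    )


# --- single-gamete simulation --------------------------------------------


def _genetic_map(track: PiecewiseTrack):
    """Cumulative genetic position (Morgans) at each track edge."""
    return np.concatenate([[0.0], np.cumsum(track.values * np.diff(track.edges)) / 1e8])


def _stationary_gamma_renewal(length: float, nu: float, rng: np.random.Generator):
    """Event positions of a unit-mean gamma(nu) renewal process on [0, length].

    Stationarity is achieved by starting the process a 30-mean-spacing burn-in
    before the origin.
    """
    if length <= 0:
        return np.empty(0)
    burn = 30.0
    n = int(math.ceil(length + burn + 8.0 * math.sqrt(length + burn) + 20.0))
    pts = np.cumsum(rng.gamma(shape=nu, scale=1.0 / nu, size=n)) - burn
    while pts[-1] < length:  # pragma: no cover - astronomically rare top-up
        pts = np.concatenate(
            [pts, pts[-1] + np.cumsum(rng.gamma(shape=nu, scale=1.0 / nu, size=n))]
        )
    return pts[(pts >= 0) & (pts < length)]


def simulate_gamete(
    classI_track: PiecewiseTrack,
    classII_track: PiecewiseTrack,
    nu: float,
    rng: np.random.Generator,
    obligate_CO: bool = False,
):
    """Draw crossover positions (bp) for one gamete on one chromosome.

    Returns ``(positions, classes)`` with positions sorted ascending and
    classes ``"I"``/``"II"``.  Events are first drawn at the bivalent level
    (twice the gamete map length) and then thinned with probability 1/2.
    """
    if nu < 1:
        raise ValueError("interference shape nu must be >= 1")
    if np.any(classI_track.values < 0) or np.any(classII_track.values < 0):
        raise ValueError("negative crossover intensity")

    mapI = _genetic_map(classI_track)  # Morgans at edges
    mapII = _genetic_map(classII_track)
    lenI, lenII = 2.0 * mapI[-1], 2.0 * mapII[-1]  # bivalent scale

    for _ in range(_MAX_OBLIGATE_REDRAWS):
        evI = _stationary_gamma_renewal(lenI, nu, rng)
        n2 = rng.poisson(lenII)
        evII = np.sort(rng.uniform(0.0, lenII, size=n2)) if lenII > 0 else np.empty(0)
        if not obligate_CO or evI.size + evII.size > 0:
            break
    else:  # pragma: no cover
        raise RuntimeError("obligate-crossover redraw limit exceeded")

    keepI = evI[rng.random(evI.size) < 0.5]
    keepII = evII[rng.random(evII.size) < 0.5]
    posI = np.interp(keepI / 2.0, mapI, classI_track.edges)
    posII = np.interp(keepII / 2.0, mapII, classII_track.edges)
    positions = np.concatenate([posI, posII])
    classes = np.concatenate([np.repeat("I", posI.size), np.repeat("II", posII.size)])
    order = np.argsort(positions, kind="stable")
    return positions[order], classes[order]


# --- F2 individuals -------------------------------------------------------


@dataclass(frozen=True)
class Gamete:
    start_phase: int  # 0 = parent A allele at position 0, 1 = parent B
    positions: np.ndarray  # crossover positions, bp, sorted
    classes: np.ndarray  # "I" / "II" per position

    def allele_at(self, pos) -> np.ndarray:
        """Parental allele (0/1) carried at position(s) ``pos``."""
        crossings = np.searchsorted(self.positions, np.asarray(pos, dtype=float), side="right")
        return (self.start_phase + crossings) % 2


@dataclass
class F2Individual:
    """One F2 plant: two meiotic products per chromosome plus its genotype mosaic."""

    id: str
    gametes: dict = field(default_factory=dict)  # chrom -> (Gamete, Gamete)
    segments: dict = field(default_factory=dict)  # chrom -> list of (start, end, "AA"|"AB"|"BB")

    @property
    def n_crossovers(self) -> int:
        return sum(g.positions.size for pair in self.gametes.values() for g in pair)

    def genotype_at(self, chrom: str, pos: float) -> str:
        g1, g2 = self.gametes[chrom]
        total = int(g1.allele_at(pos)) + int(g2.allele_at(pos))
        return ("AA", "AB", "BB")[total]


def _derive_segments(g1: Gamete, g2: Gamete, length: float):
    cuts = np.unique(np.concatenate([[0.0], g1.positions, g2.positions, [float(length)]]))
    segs = []
    for start, end in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (start + end)
        total = int(g1.allele_at(mid)) + int(g2.allele_at(mid))
        geno = ("AA", "AB", "BB")[total]
        if segs and segs[-1][2] == geno:
            segs[-1] = (segs[-1][0], end, geno)
        else:
            segs.append((start, end, geno))
    return segs


def simulate_f2_population(
    model: GenomeModel,
    params: PathwayParams,
    n: int,
    rng: np.random.Generator,
    profiles: IntensityProfiles | None = None,
):
    """Simulate ``n`` F2 individuals (two independent gametes per chromosome).

    Each individual gets an independent child RNG stream spawned from ``rng``
    so populations are reproducible regardless of per-individual draw counts.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if profiles is None:
        profiles = build_intensity_profiles(model, params)
    individuals = []
    for i, child in enumerate(rng.spawn(n)):
        ind = F2Individual(id=f"F2_{i:04d}")
        for name, length in model.chromosomes:
            pair = []
            for _ in range(2):
                pos, cls = simulate_gamete(
                    profiles.classI[name],
                    profiles.classII[name],
                    profiles.nu,
                    child,
                    obligate_CO=profiles.obligate_CO,
                )
                pair.append(Gamete(int(child.integers(2)), pos, cls))
            ind.gametes[name] = tuple(pair)
            ind.segments[name] = _derive_segments(pair[0], pair[1], length)
        individuals.append(ind)
    return individuals


def truth_calls(population) -> pd.DataFrame:
    """Ground-truth crossovers in the caller's call-table layout.

    Lets the landscape analyses run on simulated truth directly (midpoint =
    the true event position), bypassing genotyping noise.
    """
    rows = [
        {
            "individual": ind.id,
            "chrom": chrom,
            "midpoint": int(p),
            "pathway_class": c,
        }
        for ind in population
        for chrom, pair in ind.gametes.items()
        for g in pair
        for p, c in zip(g.positions, g.classes)
    ]
    return pd.DataFrame(rows, columns=["individual", "chrom", "midpoint", "pathway_class"])


# --- GBS-like marker tables ----------------------------------------------


def _marker_positions(model: GenomeModel, sites_per_Mb: float, rng: np.random.Generator):
    """Shared SNP positions, proportional to density, restricted to het blocks."""
    out = {}
    for name, length in model.chromosomes:
        density = model.snp_density[name]
        blocks = model.het_blocks.get(name, [])
        het_bp = sum(e - s for s, e in blocks)
        n_sites = int(round(sites_per_Mb * het_bp / 1e6))
        if n_sites == 0 or het_bp == 0:
            out[name] = np.empty(0, dtype=int)
            continue
        # restrict the density track to het blocks (weight 0 outside)
        edges = np.unique(
            np.concatenate([density.edges, np.array([b for blk in blocks for b in blk], float)])
        )
        edges = edges[(edges >= 0) & (edges <= length)]
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = density.value_at(mids)
        inside = np.array([model.is_het(name, m) for m in mids])
        w = np.where(inside, w, 0.0)
        if w.sum() == 0:  # flat fallback: uniform over het blocks
            w = inside.astype(float)
        cum = np.concatenate([[0.0], np.cumsum(w * np.diff(edges))])
        u = rng.uniform(0.0, cum[-1], size=n_sites)
        pos = np.interp(u, cum, edges)
        out[name] = np.unique(np.round(pos).astype(int) + 1)  # 1-based
    return out


def simulate_gbs(
    population,
    model: GenomeModel,
    mean_coverage: float = 5.0,
    error_rate: float = 0.005,
    sites_per_Mb: float = 100.0,
    rng: np.random.Generator | None = None,
    quality_fail_fraction: float = 0.05,
    base_library_reads: int = 500_000,
    coverage_shape: float = 10.0,
) -> MarkerTable:
    """Emit a sparse, noisy allele-count table for an F2 population.

    Marker sites (shared by all individuals — they are the fixed parental
    SNPs) are placed proportionally to the SNP-density track inside
    heterozygous blocks only.  Per-site depth is Poisson with an individual
    coverage multiplier (gamma, mean 1, shape ``coverage_shape``) that also
    scales the reported library size; alt reads are binomial with success
    probability 0 / 0.5 / 1 by true genotype, perturbed by ``error_rate``.
    Site mapping quality is a two-component mixture (an arbitrary scale) so a
    configurable fraction fails the ``> 100`` quality filter downstream.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng() if rng is None else rng

    sites = _marker_positions(model, sites_per_Mb, rng)
    quality = {
        name: np.where(
            rng.random(pos.size) < quality_fail_fraction,
            rng.uniform(40.0, 100.0, size=pos.size),
            rng.uniform(110.0, 250.0, size=pos.size),
        ).round(1)
        for name, pos in sites.items()
    }

    p_alt = {"AA": error_rate, "AB": 0.5, "BB": 1.0 - error_rate}
    rows = []
    library_reads = {}
    for ind in population:
        c = rng.gamma(shape=coverage_shape, scale=1.0 / coverage_shape)
        library_reads[ind.id] = int(round(c * base_library_reads))
        for name, pos in sites.items():
            if pos.size == 0:
                continue
            g1, g2 = ind.gametes[name]
            geno_idx = g1.allele_at(pos - 1) + g2.allele_at(pos - 1)
            p = np.array([error_rate, 0.5, 1.0 - error_rate])[geno_idx]
            depth = rng.poisson(mean_coverage * c, size=pos.size)
            alt = rng.binomial(depth, p)
            rows.append(
                pd.DataFrame(
                    {
                        "individual": ind.id,
                        "chrom": name,
                        "pos": pos,
                        "ref_count": depth - alt,
                        "alt_count": alt,
                        "quality": quality[name],
                    }
                )
            )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["individual", "chrom", "pos", "ref_count", "alt_count", "quality"])
    )
    df = df.sort_values(["individual", "chrom", "pos"], kind="stable").reset_index(drop=True)
    return MarkerTable(df, pd.Series(library_reads, name="library_reads"))


# --- fluorescence-class counts -------------------------------------------


def seed_class_probabilities(r: float):
    """Seed fluorescence class probabilities for a coupling-phase hemizygous F1.

    With recombination fraction ``r`` between the two seed-expressed
    transgenes and ``q = 1 - r``, selfing gives
    ``P(green only) = P(red only) = (1 - q^2)/4``, ``P(both) = (2 + q^2)/4``
    and ``P(neither) = q^2/4`` (a seed shows a colour iff at least one of its
    two gametes carries that transgene).
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError("recombination fraction must be in [0, 1]")
    q = 1.0 - r
    single = (1.0 - q * q) / 4.0
    return {
        "green_only": single,
        "red_only": single,
        "both": (2.0 + q * q) / 4.0,
        "neither": q * q / 4.0,
    }


def simulate_seed_counts(r: float, n_total: int, rng: np.random.Generator) -> SeedCountSet:
    probs = seed_class_probabilities(r)
    draw = rng.multinomial(n_total, [probs[k] for k in ("green_only", "red_only", "both", "neither")])
    return SeedCountSet(*(int(x) for x in draw))


POLLEN_8CLASS_KEYS = ("m1m2m3", "none", "m1", "m2m3", "m1m2", "m3", "m1m3", "m2")


def pollen_class_probabilities(d_b: float, d_c: float, coc: float):
    """Eight-class pollen probabilities for two adjacent intervals.

    Intervals: b between markers m1 and m2, c between m2 and m3 (ordered by
    genomic position).  Double crossovers land in the {m1+m3 only, m2 only}
    classes; single-b recombinants in {m1 only, m2+m3 only}; single-c in
    {m1+m2 only, m3 only}; the remainder is parental ({all three}, {none}).
    """
    r_b, r_c = d_b / 100.0, d_c / 100.0
    if not (0 <= r_b <= 1 and 0 <= r_c <= 1) or coc < 0:
        raise ValueError("distances must be in [0, 100] cM and coc >= 0")
    p_dco = coc * r_b * r_c
    p_sb = r_b - p_dco
    p_sc = r_c - p_dco
    p_par = 1.0 - r_b - r_c + p_dco
    if min(p_sb, p_sc, p_par) < -1e-12:
        raise ValueError("infeasible parameters: coc * r_b * r_c exceeds a class probability")
    return {
        "m1m2m3": p_par / 2,
        "none": p_par / 2,
        "m1": p_sb / 2,
        "m2m3": p_sb / 2,
        "m1m2": p_sc / 2,
        "m3": p_sc / 2,
        "m1m3": p_dco / 2,
        "m2": p_dco / 2,
    }


def simulate_pollen_counts(
    d_b: float, d_c: float, coc: float, n_total: int, rng: np.random.Generator
) -> PollenClassCounts:
    probs = pollen_class_probabilities(d_b, d_c, coc)
    draw = rng.multinomial(n_total, [probs[k] for k in POLLEN_8CLASS_KEYS])
    return PollenClassCounts(dict(zip(POLLEN_8CLASS_KEYS, (int(x) for x in draw))))


# --- interference read-out from simulated gametes ------------------------


def coc_from_gametes(gamete_positions, interval_b, interval_c):
    """Estimate the two-interval coefficient of coincidence from gametes.

    A gamete is recombinant in an interval iff it carries an odd number of
    crossovers inside it.  Returns ``(coc, d_b_cM, d_c_cM, n)``.
    """
    b0, b1 = interval_b
    c0, c1 = interval_c
    n = len(gamete_positions)
    rec_b = rec_c = dco = 0
    for pos in gamete_positions:
        pos = np.asarray(pos)
        in_b = np.count_nonzero((pos >= b0) & (pos < b1)) % 2 == 1
        in_c = np.count_nonzero((pos >= c0) & (pos < c1)) % 2 == 1
        rec_b += in_b
        rec_c += in_c
        dco += in_b and in_c
    if rec_b == 0 or rec_c == 0:
        raise ValueError("no recombinants in one of the intervals; CoC undefined")
    expected = rec_b * rec_c / n
    return dco / expected, 100.0 * rec_b / n, 100.0 * rec_c / n, n
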