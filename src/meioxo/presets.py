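"""Bundled benchmark genomes and pathway parameter sets.

These are the study conditions used by the test suite, the acceptance
script and the demo configuration: small two-chromosome genomes for caller
and landscape benchmarks, and a five-chromosome Arabidopsis-like genome
(TAIR10-scale lengths and centromeres, genome-average Col/Ler polymorphism
of 6.7 SNPs/kb) for whole-genome crossover-count simulations.
"""

from __future__ import annotations

import numpy as np

from .genome import (
    GenomeModel,
    PathwayParams,
    PiecewiseTrack,
    density_suppression_response,
    neutral_response,
)

__all__ = [
    "two_chromosome_genome",
    "gradient_genome",
    "arabidopsis_like_genome",
    "flat_pathway",
    "density_suppressed_pathway",
    "wildtype_like_pathway",
]

COL_LER_SNPS_PER_KB = 6.7  # genome-average Col x Ler polymorphism density


def two_chromosome_genome(lengths=(20_000_000, 15_000_000)) -> GenomeModel:
    """Two fully heterozygous chromosomes with uniform SNP density."""
    names = [f"chr{i + 1}" for i in range(len(lengths))]
    return GenomeModel(
        chromosomes=tuple(zip(names, lengths)),
        centromeres={n: length // 2 for n, length in zip(names, lengths)},
        snp_density={
            n: PiecewiseTrack.constant(length, COL_LER_SNPS_PER_KB)
            for n, length in zip(names, lengths)
        },
        het_blocks={n: [(0, length)] for n, length in zip(names, lengths)},
    )


def gradient_genome(length=20_000_000, n_chrom=2, lo=0.3, hi=12.0) -> GenomeModel:
    """Fully heterozygous chromosomes with a linear SNP-density gradient.

    The gradient spans ``lo``..``hi`` SNPs/kb in 20 piecewise-constant steps,
    giving the windowed density analysis a wide, known dynamic range.
    """
    edges = np.linspace(0, length, 21)
    values = np.linspace(lo, hi, 20)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    return GenomeModel(
        chromosomes=tuple((n, length) for n in names),
        centromeres={n: length // 2 for n in names},
        snp_density={n: PiecewiseTrack(edges, values) for n in names},
        het_blocks={n: [(0, length)] for n in names},
    )


# TAIR10-scale chromosome lengths and approximate centromere midpoints (bp)
_ARABIDOPSIS = (
    ("chr1", 30_400_000, 15_100_000),
    ("chr2", 19_700_000, 3_600_000),
    ("chr3", 23_500_000, 13_800_000),
    ("chr4", 18_600_000, 4_000_000),
    ("chr5", 27_000_000, 11_200_000),
)


def arabidopsis_like_genome(snps_per_kb: float = COL_LER_SNPS_PER_KB) -> GenomeModel:
    """Five-chromosome, fully heterozygous Arabidopsis-scale genome (~119 Mb)."""
    return GenomeModel(
        chromosomes=tuple((n, length) for n, length, _ in _ARABIDOPSIS),
        centromeres={n: cen for n, _, cen in _ARABIDOPSIS},
        snp_density={
            n: PiecewiseTrack.constant(length, snps_per_kb) for n, length, _ in _ARABIDOPSIS
        },
        het_blocks={n: [(0, length)] for n, length, _ in _ARABIDOPSIS},
    )


def flat_pathway(classI=3.0, classII=3.0, nu=5.0) -> PathwayParams:
    """Polymorphism-blind pathway parameters (both responses neutral)."""
    return PathwayParams(
        classI_base_cM_per_Mb=classI,
        classI_interference_shape=nu,
        classII_base_cM_per_Mb=classII,
        classI_poly_response=neutral_response,
        classII_poly_response=lambda _d: 1.0,
    )


def density_suppressed_pathway(classI=3.0, classII=5.0, nu=5.0, scale=1.0) -> PathwayParams:
    """Class II suppressed by local SNP density (multiplier 1/(1 + scale*d))."""
    return PathwayParams(
        classI_base_cM_per_Mb=classI,
        classI_interference_shape=nu,
        classII_base_cM_per_Mb=classII,
        classI_poly_response=neutral_response,
        classII_poly_response=density_suppression_response(scale),
    )


def wildtype_like_pathway() -> PathwayParams:
    """Default pathway parameters on a fully heterozygous hybrid.

    At the genome-average density of 6.7 SNPs/kb the defaults give an
    effective rate of about 3.4 cM/Mb, i.e. a ~400 cM genetic map on the
    Arabidopsis-scale genome and ~8 crossovers per F2 individual.
    """
    return PathwayParams()
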