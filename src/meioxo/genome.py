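"""Genome and crossover-pathway parameterisation.

The simulator's world is a :class:`GenomeModel`: chromosome lengths,
centromere positions, a piecewise-constant SNP-density track (SNPs/kb between
the two parental accessions) and the layout of heterozygous blocks in the F1
(everything outside a block is homozygous, hence marker-free and invisible to
genotyping).  Crossover formation is parameterised by :class:`PathwayParams`,
which separates the interference-sensitive Class I (ZMM) pathway from the
non-interfering Class II pathway and lets each respond to local polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PiecewiseTrack",
    "GenomeModel",
    "PathwayParams",
    "boundary_stimulation_response",
    "density_suppression_response",
    "neutral_response",
]


class PiecewiseTrack:
    """Piecewise-constant non-negative track on ``[0, length)``.

    ``edges`` are the ``n + 1`` breakpoints (first 0, last the chromosome
    length); ``values[i]`` holds on ``[edges[i], edges[i+1])``.
    """

    def __init__(self, edges: Sequence[float], values: Sequence[float]):
        edges = np.asarray(edges, dtype=float)
        values = np.asarray(values, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if values.shape != (edges.size - 1,):
            raise ValueError("values must have len(edges) - 1 entries")
        if not np.all(np.isfinite(values)):
            raise ValueError("track values must be finite")
        self.edges = edges
        self.values = values

    @classmethod
    def constant(cls, length: float, value: float) -> "PiecewiseTrack":
        return cls([0.0, float(length)], [value])

    @property
    def length(self) -> float:
        return float(self.edges[-1])

    def value_at(self, x):
        """Track value at position(s) ``x`` (right-open intervals)."""
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, self.values.size - 1)
        return self.values[idx]

    def integral(self) -> float:
        return float(np.sum(self.values * np.diff(self.edges)))

    def cumulative(self):
        """Cumulative integral at each edge (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.values * np.diff(self.edges))])


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome layout shared by the simulator and the landscape analysis.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs.
    centromeres
        Centromere position (bp) per chromosome name.
    snp_density
        Per-chromosome :class:`PiecewiseTrack` of SNPs/kb.  Density should be
        ~0 inside homozygous blocks (the two parental genomes are identical
        there); :meth:`validate` does not enforce this, the model builder in
        :mod:`meioxo.config` does.
    het_blocks
        Per-chromosome sorted, non-overlapping half-open ``(start, end)`` bp
        intervals that are heterozygous in the F1.
    """

    chromosomes: tuple
    centromeres: dict
    snp_density: dict
    het_blocks: dict

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            cen = self.centromeres.get(name)
            if cen is None or not (0 < cen < length):
                raise ValueError(f"centromere of {name!r} missing or outside chromosome")
            track = self.snp_density.get(name)
            if track is None:
                raise ValueError(f"no SNP-density track for {name!r}")
            if np.any(track.values < 0):
                raise ValueError(f"negative SNP density on {name!r}")
            blocks = self.het_blocks.get(name, [])
            prev_end = 0
            for start, end in blocks:
                if not (0 <= start < end <= length):
                    raise ValueError(f"het block {start}-{end} outside {name!r}")
                if start < prev_end:
                    raise ValueError(f"het blocks overlap or unsorted on {name!r}")
                prev_end = end

    @property
    def names(self):
        return [name for name, _ in self.chromosomes]

    def length_of(self, name: str) -> int:
        for n, length in self.chromosomes:
            if n == name:
                return length
        raise KeyError(name)

    def is_het(self, name: str, pos: float) -> bool:
        return any(s <= pos < e for s, e in self.het_blocks.get(name, []))

    def boundary_distance(self, name: str, pos: float) -> float:
        """Distance (bp) to the nearest heterozygous/homozygous boundary.

        Chromosome ends do not count as boundaries; a chromosome that is
        heterozygous end-to-end has no boundary (returns ``inf``).
        """
        length = self.length_of(name)
        dists = []
        for start, end in self.het_blocks.get(name, []):
            if start > 0:
                dists.append(abs(pos - start))
            if end < length:
                dists.append(abs(pos - end))
        return min(dists) if dists else float("inf")


# --- polymorphism-response factories -------------------------------------
#
# Class I responses take (snps_per_kb, boundary_dist_bp) and return a
# multiplier >= 0; Class II responses take snps_per_kb and return a
# multiplier in [0, 1].


def neutral_response(*_args) -> float:
    return 1.0


def boundary_stimulation_response(amplitude: float = 1.0, length_scale_bp: float = 300_000.0) -> Callable:
    """Class I stimulation near heterozygosity-block boundaries.

    Multiplier ``1 + A * exp(-d / L)`` with ``d`` the distance to the nearest
    HET/HOM boundary.  A minimal, illustrative emulation of the juxtaposition
    effect — not fitted to data.
    """
    if amplitude < 0 or length_scale_bp <= 0:
        raise ValueError("amplitude must be >= 0 and length scale > 0")

    def response(_density: float, boundary_dist: float) -> float:
        if not np.isfinite(boundary_dist):
            return 1.0
        return 1.0 + amplitude * float(np.exp(-boundary_dist / length_scale_bp))

    return response


def density_suppression_response(scale: float = 1.0) -> Callable:
    """Class II inhibition rising with local SNP density: ``1 / (1 + s * d)``."""
    if scale < 0:
        raise ValueError("scale must be >= 0")

    def response(density: float) -> float:
        return 1.0 / (1.0 + scale * float(density))

    return response


@dataclass
class PathwayParams:
    """Class I / Class II crossover pathway parameters.

    ``classI_interference_shape`` is the gamma-renewal shape ``nu``; ``nu = 1``
    reduces Class I to a Poisson (no-interference) process.  ``msh2_active``
    models a functional MSH2 mismatch-detection pathway: when True the
    polymorphism responses apply; when False both responses are neutral except
    a residual, MSH2-independent Class II inhibition at very high density.
    """

    classI_base_cM_per_Mb: float = 3.0
    classI_interference_shape: float = 5.0
    classII_base_cM_per_Mb: float = 3.0
    classI_poly_response: Callable = field(default_factory=boundary_stimulation_response)
    classII_poly_response: Callable = field(default_factory=density_suppression_response)
    residual_classII_inhibition: Callable = field(
        default_factory=lambda: density_suppression_response(scale=0.05)
    )
    msh2_active: bool = True
    obligate_CO: bool = False

    def validate(self) -> None:
        if self.classI_base_cM_per_Mb < 0 or self.classII_base_cM_per_Mb < 0:
            raise ValueError("base rates must be >= 0")
        if self.classI_interference_shape < 1:
            raise ValueError("interference shape nu must be >= 1")
        for fn in (self.classI_poly_response, self.classII_poly_response,
                   self.residual_classII_inhibition):
            if not callable(fn):
                raise ValueError("response specs must be callable")

    def classI_multiplier(self, density: float, boundary_dist: float) -> float:
        m = self.classI_poly_response(density, boundary_dist) if self.msh2_active else 1.0
        if not np.isfinite(m) or m < 0:
            raise ValueError("Class I response produced an invalid multiplier")
        return float(m)

    def classII_multiplier(self, density: float) -> float:
        if self.msh2_active:
            m = self.classII_poly_response(density)
        else:
            m = self.residual_classII_inhibition(density)
        if not np.isfinite(m) or not (0 <= m <= 1):
            raise ValueError("Class II response multiplier must be in [0, 1]")
        return float(m)
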