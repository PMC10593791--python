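"""Structured run configuration: schema validation and model construction.

One YAML document drives a whole run: genome layout, pathway parameters,
simulator sample sizes, caller filters and landscape windows, plus the root
RNG seed.  Unknown keys are rejected by name; defaults are filled in and
echoed so the manifest records the complete effective configuration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

from .genome import (
    GenomeModel,
    PathwayParams,
    PiecewiseTrack,
    boundary_stimulation_response,
    density_suppression_response,
)

__all__ = ["RunConfig", "validate_config", "config_hash"]

_DEFAULTS = {
    "seed": 0,
    "out_dir": "meioxo_out",
    "log_level": "INFO",
    "genome": {
        "chromosomes": [],  # list of {name, length, centromere}
        "het_blocks": {},  # chrom -> [[start, end], ...]; default: fully heterozygous
        "snp_density": {},  # chrom -> constant SNPs/kb or {edges: [...], values: [...]}
    },
    "pathway": {
        "classI_base_cM_per_Mb": 3.0,
        "classI_interference_shape": 5.0,
        "classII_base_cM_per_Mb": 3.0,
        "msh2_active": True,
        "obligate_co": False,
        "boundary_amplitude": 1.0,
        "boundary_length_bp": 300_000.0,
        "classII_suppression_scale": 1.0,
        "residual_suppression_scale": 0.05,
    },
    "simulator": {
        "n_individuals": 200,
        "mean_coverage": 5.0,
        "error_rate": 0.005,
        "sites_per_mb": 100.0,
        "quality_fail_fraction": 0.05,
        "base_library_reads": 500_000,
    },
    "caller": {
        "min_site_quality": 100.0,
        "min_mean_coverage": 2.5,
        "min_library_reads": 100_000,
        "smoothing_window": 5,
        "min_support": 3,
        "hom_fraction": 0.1,
    },
    "landscape": {
        "window_bp": 300_000,
        "density_window_bp": 100_000,
        "group_size": 12,
        "loess_span": 0.75,
        "arm_bins": 50,
        "drop_partial": False,
    },
}

_POSITIVE_KEYS = {
    ("simulator", "n_individuals"),
    ("simulator", "mean_coverage"),
    ("simulator", "sites_per_mb"),
    ("landscape", "window_bp"),
    ("landscape", "density_window_bp"),
    ("landscape", "group_size"),
    ("landscape", "arm_bins"),
}
_NON_NEGATIVE_KEYS = {
    ("caller", "min_site_quality"),
    ("caller", "min_mean_coverage"),
    ("caller", "min_library_reads"),
    ("simulator", "error_rate"),
    ("pathway", "classI_base_cM_per_Mb"),
    ("pathway", "classII_base_cM_per_Mb"),
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted run configuration."""

    raw: dict = field(repr=False)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def section(self, name: str) -> dict:
        return self.raw[name]

    def genome_model(self) -> GenomeModel:
        g = self.raw["genome"]
        if not g["chromosomes"]:
            raise ValueError("genome.chromosomes is empty")
        chroms = tuple((c["name"], int(c["length"])) for c in g["chromosomes"])
        centromeres = {c["name"]: int(c["centromere"]) for c in g["chromosomes"]}
        het = {
            name: [tuple(b) for b in g["het_blocks"].get(name, [[0, length]])]
            for name, length in chroms
        }
        density = {}
        for name, length in chroms:
            spec = g["snp_density"].get(name, 6.7)  # Col/Ler genome-average SNPs/kb
            if isinstance(spec, dict):
                density[name] = PiecewiseTrack(spec["edges"], spec["values"])
            else:
                density[name] = PiecewiseTrack.constant(length, float(spec))
        return GenomeModel(chroms, centromeres, density, het)

    def pathway_params(self) -> PathwayParams:
        p = self.raw["pathway"]
        return PathwayParams(
            classI_base_cM_per_Mb=float(p["classI_base_cM_per_Mb"]),
            classI_interference_shape=float(p["classI_interference_shape"]),
            classII_base_cM_per_Mb=float(p["classII_base_cM_per_Mb"]),
            classI_poly_response=boundary_stimulation_response(
                float(p["boundary_amplitude"]), float(p["boundary_length_bp"])
            ),
            classII_poly_response=density_suppression_response(
                float(p["classII_suppression_scale"])
            ),
            residual_classII_inhibition=density_suppression_response(
                float(p["residual_suppression_scale"])
            ),
            msh2_active=bool(p["msh2_active"]),
            obligate_CO=bool(p["obligate_co"]),
        )


def _merge(defaults: dict, user: dict, path: str = ""):
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            value = user[key]
            if isinstance(default, dict) and path == "" and key != "genome":
                if not isinstance(value, dict):
                    raise ValueError(f"config section {here!r} must be a mapping")
                out[key] = _merge(default, value, here)
            elif key == "genome":
                out[key] = _merge(default, value, here)
            else:
                out[key] = value
        else:
            out[key] = {k: v for k, v in default.items()} if isinstance(default, dict) else default
    unknown = set(user) - set(defaults)
    if unknown:
        where = f" in section {path!r}" if path else ""
        raise ValueError(f"unknown config key(s) {sorted(unknown)}{where}")
    return out


def validate_config(source) -> RunConfig:
    """Load and validate a config from a path, YAML string or dict."""
    if isinstance(source, dict):
        user = source
    else:
        text = source if "\n" in str(source) else None
        if text is None:
            with open(source) as fh:
                user = yaml.safe_load(fh) or {}
        else:
            user = yaml.safe_load(text) or {}
    merged = _merge(_DEFAULTS, user)
    for section, key in _POSITIVE_KEYS:
        if merged[section][key] <= 0:
            raise ValueError(f"config key {section}.{key} must be positive")
    for section, key in _NON_NEGATIVE_KEYS:
        if merged[section][key] < 0:
            raise ValueError(f"config key {section}.{key} must be >= 0")
    if merged["caller"]["smoothing_window"] % 2 != 1:
        raise ValueError("config key caller.smoothing_window must be odd")
    cfg = RunConfig(raw=merged)
    if merged["genome"]["chromosomes"]:
        cfg.genome_model()  # fail early if the genome section is inconsistent
    cfg.pathway_params().validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    canonical = yaml.safe_dump(cfg.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
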