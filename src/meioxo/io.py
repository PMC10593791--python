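"""Plain-text format adapters: marker TSV, BED, CSV count tables, VCF ingestion.

Every writer prepends ``#``-prefixed header comment lines carrying the tool
version, the configuration hash and the RNG seed of the run that produced
the file; every reader skips them.  Marker positions are 1-based in tables
and converted to 0-based half-open coordinates in BED output.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import __version__
from .caller import MARKER_COLUMNS, MarkerTable
from .ftl import EIGHT_CLASS_KEYS, FOUR_CLASS_KEYS, PollenClassCounts, SeedCountSet

__all__ = [
    "header_lines",
    "write_marker_table",
    "read_marker_table",
    "write_truth_bed",
    "write_calls",
    "read_calls",
    "write_table",
    "read_table",
    "read_seed_counts",
    "read_pollen_counts",
    "convert_vcf_to_marker_table",
    "sha256_of",
]

_LIBRARY_PREFIX = "#library_reads\t"


def header_lines(seed=None, config_hash=None):
    lines = [f"#meioxo v{__version__}"]
    if seed is not None:
        lines.append(f"#seed={seed}")
    if config_hash is not None:
        lines.append(f"#config_hash={config_hash}")
    return lines


def _write_with_header(df: pd.DataFrame, path, sep, seed, config_hash, extra=(), index=False):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        for line in extra:
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=index)


def write_marker_table(table: MarkerTable, path, seed=None, config_hash=None) -> None:
    extra = [
        f"{_LIBRARY_PREFIX}{ind}\t{int(reads)}" for ind, reads in table.library_reads.items()
    ]
    _write_with_header(table.df[MARKER_COLUMNS], path, "\t", seed, config_hash, extra)


def read_marker_table(path) -> MarkerTable:
    path = Path(path)
    library = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith(_LIBRARY_PREFIX):
                _, ind, reads = line.rstrip("\n").split("\t")
                library[ind] = int(reads)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not library:  # fall back: infer library sizes from on-target reads
        library = (df["ref_count"] + df["alt_count"]).groupby(df["individual"]).sum().to_dict()
    return MarkerTable(df, pd.Series(library, name="library_reads"))


def write_truth_bed(population, path, seed=None, config_hash=None) -> None:
    """Ground-truth crossovers as BED3+ (chrom, start, end, individual, class)."""
    rows = []
    for ind in population:
        for chrom, pair in ind.gametes.items():
            for g in pair:
                for pos, cls in zip(g.positions, g.classes):
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": max(int(pos) - 1, 0),
                            "end": int(pos),
                            "individual": ind.id,
                            "pathway_class": cls,
                        }
                    )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "individual", "pathway_class"])
    df = df.sort_values(["chrom", "start", "individual"], kind="stable")
    _write_with_header(df, path, "\t", seed, config_hash)


def write_calls(calls: pd.DataFrame, bed_path=None, tsv_path=None, seed=None, config_hash=None):
    """Crossover calls as BED6-like (midpoint interval) and/or a full TSV."""
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": calls["chrom"],
                "start": calls["midpoint"] - 1,
                "end": calls["midpoint"],
                "individual": calls["individual"],
                "score": 0,
                "transition": calls["transition"],
            }
        )
        _write_with_header(bed, bed_path, "\t", seed, config_hash)
    if tsv_path is not None:
        _write_with_header(calls, tsv_path, "\t", seed, config_hash)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, sep=None, seed=None, config_hash=None) -> None:
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".bed")) else ",")
    _write_with_header(df, path, sep, seed, config_hash)


def read_table(path, sep=None) -> pd.DataFrame:
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".bed")) else ",")
    return pd.read_csv(path, sep=sep, comment="#")


def read_seed_counts(path) -> SeedCountSet:
    """Seed class counts from a one-row CSV with the four class columns."""
    df = read_table(path, sep=",")
    row = df.iloc[0]
    return SeedCountSet(
        n_green_only=int(row["green_only"]),
        n_red_only=int(row["red_only"]),
        n_both=int(row["both"]),
        n_neither=int(row["neither"]),
    )


def read_pollen_counts(path) -> PollenClassCounts:
    """Pollen class counts from a one-row CSV whose header names the classes."""
    df = read_table(path, sep=",")
    counts = {k: int(df.iloc[0][k]) for k in df.columns}
    if not (set(counts) == EIGHT_CLASS_KEYS or set(counts) == FOUR_CLASS_KEYS):
        raise ValueError("pollen CSV header must name the 4- or 8-class keys")
    return PollenClassCounts(counts)


def convert_vcf_to_marker_table(vcf_path, sample_map: dict | None = None) -> tuple:
    """Biallelic SNP allele depths from a VCF with per-sample AD fields.

    ``sample_map`` renames VCF samples to individual ids (default identity).
    Returns ``(MarkerTable, n_multiallelic_skipped)``; library sizes are the
    summed allele depths per sample.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sample_map = sample_map or {s: s for s in samples}
    rows = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(f"no AD (allelic depth) field for record at {variant.CHROM}:{variant.POS}")
        for s, sample in enumerate(samples):
            ref, alt = (max(int(v), 0) for v in ad[s][:2])
            rows.append(
                {
                    "individual": sample_map[sample],
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "ref_count": ref,
                    "alt_count": alt,
                    "quality": variant.QUAL if variant.QUAL is not None else 0.0,
                }
            )
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    df = df.sort_values(["individual", "chrom", "pos"], kind="stable").reset_index(drop=True)
    library = (df["ref_count"] + df["alt_count"]).groupby(df["individual"]).sum()
    return MarkerTable(df, library.rename("library_reads")), skipped


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
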