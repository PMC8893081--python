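"""Readers and writers for the pipeline's tabular formats, plus run config.

Formats
-------
* trial table: long-format TSV/CSV with header
  ``environment, plot, plant, genotype, trait, value`` (plant may be empty
  for plot-level traits);
* SNP calls: TSV ``chrom, pos, child, recurrent, donor`` with calls in
  ``{0/0, 1/1, 0/1, ./.}``, or a VCF with the three samples;
* marker matrix: individuals x markers CSV with alleles ``{A, B, H, -}``;
* phenotypes: two-column TSV ``individual, value``;
* recovery regions: BED (0-based half-open);
* run configuration: flat YAML, unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .recovery import Call, RecoveryRegion
from .trial import TRAITS

__all__ = [
    "RunConfig",
    "read_trial_table",
    "write_trial_table",
    "read_snp_calls_tsv",
    "read_snp_calls_vcf",
    "read_marker_matrix",
    "read_phenotypes",
    "write_regions_bed",
    "write_effects_tsv",
    "load_config",
]


@dataclasses.dataclass
class RunConfig:
    """Flat pipeline configuration; defaults match the published analysis."""

    trial_table: str | None = None
    snp_calls: str | None = None
    marker_matrix: str | None = None
    phenotypes: str | None = None
    output_dir: str = "nilgenetics_out"
    traits: tuple[str, ...] = tuple(TRAITS)
    window_size: int = 15
    step: int = 1
    breakpoint_threshold: int = 8
    genome_length_bp: int | None = None
    alpha: float = 0.05
    bulk_size: int = 12
    n_environments: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [t for t in self.traits if t not in TRAITS]
        if unknown:
            raise ValueError(f"unknown traits in config: {unknown}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def load_config(path) -> RunConfig:
    """Load a flat YAML config; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "traits" in raw:
        raw["traits"] = tuple(raw["traits"])
    return RunConfig(**raw)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Errors name the offending row (1-based, excluding the header) and the
    offending trait label or value.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = ["environment", "plot", "genotype", "trait", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "plant" not in df.columns:
        df["plant"] = ""
    for i, trait in enumerate(df["trait"], start=1):
        if trait not in TRAITS:
            raise ValueError(f"{path}: row {i}: unknown trait label {trait!r}")
    values = np.empty(len(df))
    for i, v in enumerate(df["value"], start=1):
        try:
            values[i - 1] = float(v)
        except ValueError:
            raise ValueError(f"{path}: row {i}: non-numeric value {v!r}") from None
        if not np.isfinite(values[i - 1]):
            raise ValueError(f"{path}: row {i}: non-finite value {v!r}")
    out = df[["environment", "plot", "plant", "genotype", "trait"]].copy()
    out["value"] = values
    return out


def write_trial_table(df: pd.DataFrame, path) -> None:
    cols = ["environment", "plot", "plant", "genotype", "trait", "value"]
    df.loc[:, cols].to_csv(path, sep=_sep_for(path), index=False)


def read_snp_calls_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a ``chrom, pos, child, recurrent, donor`` call table.

    Returns the three per-sample frames (chrom, pos, call) expected by the
    genome-recovery functions.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "child", "recurrent", "donor"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frames = []
    for col in ("child", "recurrent", "donor"):
        sub = df[["chrom", "pos"]].copy()
        sub["call"] = [Call.from_string(str(v)) for v in df[col]]
        frames.append(sub)
    return tuple(frames)  # type: ignore[return-value]


def read_snp_calls_vcf(
    path, child: str, recurrent: str, donor: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read three samples' biallelic SNP calls from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        idx = [samples.index(s) for s in (child, recurrent, donor)]
    except ValueError as exc:
        raise ValueError(f"{path}: sample not found ({exc}); has {samples}") from None
    rows: list[list] = [[], [], []]
    code_to_call = {0: Call.REF_HOM, 1: Call.HET, 2: Call.MISSING, 3: Call.ALT_HOM}
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        for k, si in enumerate(idx):
            rows[k].append((var.CHROM, var.POS, code_to_call[var.gt_types[si]]))
    return tuple(
        pd.DataFrame(r, columns=["chrom", "pos", "call"]) for r in rows
    )  # type: ignore[return-value]


def read_marker_matrix(path) -> pd.DataFrame:
    """Individuals x markers allele matrix (first column = individual ID)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df = df.set_index(df.columns[0])
    valid = {"A", "B", "H", "-"}
    bad = sorted(set(np.unique(df.to_numpy())) - valid)
    if bad:
        raise ValueError(f"{path}: invalid allele codes {bad}; expected {sorted(valid)}")
    return df


def read_phenotypes(path) -> pd.Series:
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype table needs two columns (id, value)")
    s = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name=df.columns[1],
    )
    return s


def write_regions_bed(regions: Iterable[RecoveryRegion], path) -> None:
    """Write recovery regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\trecovered\n")


def write_effects_tsv(effects: pd.DataFrame, path, decimals: int = 4) -> None:
    """Write a tidy effects table rounded for display; a *_raw companion
    keeps full precision."""
    path = Path(path)
    rounded = effects.copy()
    rounded["value"] = rounded["value"].round(decimals)
    rounded.to_csv(path, sep="\t", index=False)
    raw = path.with_name(path.stem + "_raw" + path.suffix)
    effects.to_csv(raw, sep="\t", index=False)
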