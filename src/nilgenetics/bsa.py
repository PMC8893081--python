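"""Bulked-segregant analysis and single-marker QTL scanning on DH lines.

A doubled-haploid (DH) population is fully homozygous, so each individual
carries either the recurrent-type allele ``A`` or the donor-type allele
``B`` at every marker; heterozygous calls are genotyping errors and are
dropped with a warning.

*Bulk construction* takes the k most extreme individuals at each phenotypic
tail (k = 12 by default).  *Co-segregation screening* reports markers whose
alleles separate the two bulks perfectly (or within ``max_mismatch`` stray
alleles) -- the in-silico analogue of a pooled-DNA band difference, where a
bulk shows an allele iff any member carries it.

*Single-marker scan*: per marker, a one-way two-group analysis of the
phenotype gives the fraction of phenotypic variance explained,

    PVE = 100 * SS_between / SS_total ,
    LOD = -(n / 2) * log10(1 - SS_between / SS_total) ,

with the usual F statistic and p-value.  This is a deliberate, clearly
labelled single-marker substitute for interval-mapping software: adequate
for locating major loci and for validating simulations, not a linkage-map
method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = ["BulkPair", "ScanResult", "select_bulks", "cosegregation_screen", "marker_scan"]

ALLELES = ("A", "B", "H", "-")  # '-' encodes missing


@dataclass(frozen=True)
class BulkPair:
    """Disjoint sets of extreme-phenotype individuals."""

    early: tuple[str, ...]
    late: tuple[str, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if set(self.early) & set(self.late):
            raise ValueError("early and late bulks overlap")


@dataclass(frozen=True)
class ScanResult:
    """Single-marker association: F, p, LOD, and percent variance explained."""

    marker: str
    f_statistic: float
    p_value: float
    lod: float
    pve_percent: float
    n: int


def select_bulks(phenotypes: Mapping[str, float] | pd.Series, k: int = 12) -> BulkPair:
    """The k lowest- and k highest-phenotype individuals, ties broken by ID.

    With every phenotype equal the split is still deterministic (ID order)
    but flagged ``degenerate``.
    """
    if isinstance(phenotypes, pd.Series):
        phenotypes = phenotypes.to_dict()
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > len(phenotypes):
        raise ValueError(
            f"need at least 2k={2 * k} phenotyped individuals, got {len(phenotypes)}"
        )
    order = sorted(phenotypes, key=lambda i: (phenotypes[i], str(i)))
    early = tuple(order[:k])
    late = tuple(sorted(order[-k:], key=lambda i: (-phenotypes[i], str(i))))
    degenerate = phenotypes[order[0]] == phenotypes[order[-1]]
    return BulkPair(early=early, late=late, degenerate=degenerate)


def cosegregation_screen(
    genotypes: pd.DataFrame, bulks: BulkPair, max_mismatch: int = 0
) -> list[str]:
    """Markers whose alleles co-segregate with the bulks.

    ``genotypes`` is an individuals x markers frame with alleles in
    ``{A, B, H, -}``.  A marker passes when, in one orientation or the
    other, at most ``max_mismatch`` typed alleles deviate from the pattern
    "all A in one bulk, all B in the other".  Missing calls are not counted
    as mismatches; a marker untyped in an entire bulk is skipped with a
    warning.
    """
    early = genotypes.loc[list(bulks.early)].to_numpy(dtype=str)
    late = genotypes.loc[list(bulks.late)].to_numpy(dtype=str)
    typed = ("A", "B", "H")
    e_typed = np.isin(early, typed)
    l_typed = np.isin(late, typed)
    untyped = (e_typed.sum(axis=0) == 0) | (l_typed.sum(axis=0) == 0)
    for marker in genotypes.columns[untyped]:
        logger.warning("marker %s untyped in an entire bulk; skipped", marker)
    # orientation 1: early all A, late all B; orientation 2: reversed
    mm1 = ((early != "A") & e_typed).sum(axis=0) + ((late != "B") & l_typed).sum(axis=0)
    mm2 = ((early != "B") & e_typed).sum(axis=0) + ((late != "A") & l_typed).sum(axis=0)
    passing = (np.minimum(mm1, mm2) <= max_mismatch) & ~untyped
    return [str(m) for m, ok in zip(genotypes.columns, passing) if ok]


def marker_scan(
    genotypes: pd.DataFrame,
    phenotypes: Mapping[str, float] | pd.Series,
    min_class_size: int = 3,
) -> list[ScanResult]:
    """One-way two-group association scan over every polymorphic marker.

    Individuals with heterozygous or missing calls at a marker are excluded
    there (DH heterozygotes are treated as errors).  Markers monomorphic
    after exclusion, or with a class smaller than ``min_class_size``, are
    skipped.
    """
    if isinstance(phenotypes, Mapping):
        phenotypes = pd.Series(phenotypes, dtype=float)
    common = [i for i in genotypes.index if i in phenotypes.index]
    if not common:
        raise ValueError("no phenotyped individuals among the genotyped ones")
    geno = genotypes.loc[common]
    pheno = phenotypes.loc[common].to_numpy(float)

    n_het_dropped = 0
    results: list[ScanResult] = []
    for marker in geno.columns:
        alleles = geno[marker].astype(str).to_numpy()
        n_het_dropped += int(np.sum(alleles == "H"))
        mask_a = alleles == "A"
        mask_b = alleles == "B"
        ya, yb = pheno[mask_a], pheno[mask_b]
        if len(ya) < min_class_size or len(yb) < min_class_size:
            continue
        y = np.concatenate([ya, yb])
        n = y.size
        grand = y.mean()
        ss_total = float(np.sum((y - grand) ** 2))
        ss_between = float(
            len(ya) * (ya.mean() - grand) ** 2 + len(yb) * (yb.mean() - grand) ** 2
        )
        if ss_total == 0:
            r2 = 0.0
        else:
            r2 = ss_between / ss_total
        r2 = min(r2, 1.0)
        df_w = n - 2
        ss_within = max(ss_total - ss_between, 0.0)
        if ss_within == 0:
            f = np.inf if ss_between > 0 else 0.0
        else:
            f = (ss_between / 1.0) / (ss_within / df_w)
        p = float(scipy.stats.f.sf(f, 1, df_w)) if np.isfinite(f) else 0.0
        lod = np.inf if r2 >= 1.0 else float(-(n / 2.0) * np.log10(1.0 - r2))
        results.append(
            ScanResult(
                marker=str(marker),
                f_statistic=float(f),
                p_value=p,
                lod=max(lod, 0.0),
                pve_percent=100.0 * r2,
                n=n,
            )
        )
    if n_het_dropped:
        logger.warning(
            "marker_scan: dropped %d heterozygous DH calls as errors", n_het_dropped
        )
    return results
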