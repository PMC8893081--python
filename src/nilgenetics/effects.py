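"""Genetic-effect decomposition and mid-parent heterosis.

Given the BLUE of each of the 27 three-locus genotypes for a trait, the
saturated additive-dominance-epistasis system is exactly identified: the
27 x 27 design matrix is invertible, so the effect vector is obtained by a
single linear solve rather than least squares.  A reduced additive-epistasis
variant operates on the 8 homozygous genotypes alone (m, a x3, aa x3, aaa);
its +-1 coding matrix H satisfies ``effects = H^T y / 8``.

Mid-parent heterosis (MPH) of an F1 hybrid is the percent deviation of its
trait value from the mid-parent value MP = (p1 + p2) / 2:

    MPH = 100 * (F1 - MP) / MP .

Hybrids are classified against the mid-parent flowering time: Group II
hybrids flower significantly later than the mid-parent (difference beyond
the LSD); Group I hybrids flower earlier or not significantly differently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    EFFECT_NAMES,
    HOMOZYGOUS_EFFECT_NAMES,
    EffectVector,
    all_genotypes,
    design_matrix,
    homozygous_genotypes,
)
from .trial import TRAITS

__all__ = [
    "GroupLabel",
    "HeterosisRecord",
    "solve_effects",
    "solve_homozygous_effects",
    "mid_parent_heterosis",
    "classify_hybrid_group",
    "heterosis_table",
    "effects_frame",
]


class GroupLabel(enum.Enum):
    GROUP_I = "I"
    GROUP_II = "II"


@dataclass(frozen=True)
class HeterosisRecord:
    """Mid-parent heterosis of one hybrid for one trait."""

    hybrid_id: str
    parent1_id: str
    parent2_id: str
    trait: str
    f1: float
    mid_parent: float
    mph_percent: float


def _trait_means(means, trait: str | None) -> pd.Series:
    if isinstance(means, pd.DataFrame):
        if trait is None:
            raise ValueError("a trait label is required with a multi-trait table")
        if trait not in means.columns:
            raise KeyError(f"trait {trait!r} not in BLUE table")
        return means[trait]
    if isinstance(means, Mapping):
        return pd.Series(means, dtype=float)
    return pd.Series(means, dtype=float)


def solve_effects(means, trait: str | None = None, metric: str = "finf") -> EffectVector:
    """Exact 27-component effect vector from the 27 genotype means.

    ``means`` maps genotype ID -> BLUE (Series/dict) or is a genotype x
    trait DataFrame with ``trait`` selecting the column.  All 27 genotypes
    must be present; absentees are listed in the error.
    """
    y = _trait_means(means, trait)
    genotypes = all_genotypes()
    missing = [g.id for g in genotypes if g.id not in y.index]
    if missing:
        raise ValueError(f"solve_effects needs all 27 genotype means; missing: {missing}")
    X = design_matrix(genotypes, metric=metric)
    sol = np.linalg.solve(X.to_numpy(), y.loc[X.index].to_numpy(float))
    return EffectVector.from_array(sol)


def solve_homozygous_effects(means, trait: str | None = None) -> pd.Series:
    """Reduced additive-epistasis decomposition from the 8 homozygous means.

    Returns the 8 components (m, a_A2, a_C2, a_A3, aa_A2C2, aa_A2A3,
    aa_C2A3, aaa) as a Series.  Equivalent to ``H^T y / 8`` for the +-1
    coding matrix H.
    """
    y = _trait_means(means, trait)
    genotypes = homozygous_genotypes()
    missing = [g.id for g in genotypes if g.id not in y.index]
    if missing:
        raise ValueError(
            f"solve_homozygous_effects needs all 8 homozygous means; missing: {missing}"
        )
    X = design_matrix(genotypes).loc[:, list(HOMOZYGOUS_EFFECT_NAMES)]
    sol = np.linalg.solve(X.to_numpy(), y.loc[X.index].to_numpy(float))
    return pd.Series(sol, index=list(HOMOZYGOUS_EFFECT_NAMES), dtype=float)


def mid_parent_heterosis(f1: float, p1: float, p2: float) -> float:
    """Percent mid-parent heterosis ``100 * (f1 - MP) / MP``."""
    mp = (p1 + p2) / 2.0
    if mp == 0:
        raise ZeroDivisionError("mid-parent value is zero; heterosis undefined")
    return float(100.0 * (f1 - mp) / mp)


def classify_hybrid_group(
    f1_ft: float, p1_ft: float, p2_ft: float, lsd: float
) -> GroupLabel:
    """Group II iff the hybrid flowers later than the mid-parent by > LSD."""
    if lsd <= 0:
        raise ValueError("lsd must be positive")
    mp = (p1_ft + p2_ft) / 2.0
    return GroupLabel.GROUP_II if f1_ft - mp > lsd else GroupLabel.GROUP_I


def heterosis_table(
    blues: pd.DataFrame,
    pedigree: Sequence[tuple[str, str, str]],
    traits: Sequence[str] | None = None,
) -> list[HeterosisRecord]:
    """Mid-parent heterosis of every hybrid for every trait.

    ``blues`` is genotype x trait; ``pedigree`` lists
    (hybrid_id, parent1_id, parent2_id).  One record per hybrid x trait.
    """
    traits = list(traits) if traits is not None else [t for t in blues.columns]
    unknown = [t for t in traits if t not in TRAITS]
    if unknown:
        raise ValueError(f"unknown trait labels: {unknown}")
    records = []
    for hybrid, p1, p2 in pedigree:
        for gid in (hybrid, p1, p2):
            if gid not in blues.index:
                raise KeyError(f"genotype {gid!r} missing from BLUE table")
        for trait in traits:
            f1 = float(blues.loc[hybrid, trait])
            v1 = float(blues.loc[p1, trait])
            v2 = float(blues.loc[p2, trait])
            mp = (v1 + v2) / 2.0
            records.append(
                HeterosisRecord(
                    hybrid_id=hybrid,
                    parent1_id=p1,
                    parent2_id=p2,
                    trait=trait,
                    f1=f1,
                    mid_parent=mp,
                    mph_percent=mid_parent_heterosis(f1, v1, v2),
                )
            )
    return records


def effects_frame(blues: pd.DataFrame, metric: str = "finf") -> pd.DataFrame:
    """Tidy (trait, component, value) table of full decompositions per trait."""
    rows = []
    for trait in blues.columns:
        e = solve_effects(blues, trait, metric=metric)
        for name, value in zip(EFFECT_NAMES, e.values):
            rows.append((trait, name, value))
    return pd.DataFrame(rows, columns=["trait", "component", "value"])
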