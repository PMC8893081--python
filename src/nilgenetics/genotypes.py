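"""Three-locus NIL genotype space and the additive-dominance-epistasis design.

The package models a set of near-isogenic rapeseed lines (NILs) segregating at
three flowering-time loci -- *BnFLC.A2*, *BnFLC.C2* and *BnFLC.A3b* -- in a
common recurrent-parent background.  Each locus is in one of three states:

* ``0`` -- homozygous for the early-flowering (mutated, non-functional) allele,
* ``1`` -- homozygous for the late-flowering (wild-type, functional) allele,
* ``2`` -- heterozygous.

A genotype is an ordered triple of these digits, carried in an ID string such
as ``"ID15-222"`` (the triple heterozygote).  The eight homozygous genotypes
are ``ID01-000`` ... ``ID08-111``; the 19 hybrids with at least one
heterozygous locus are ``ID09-020`` ... ``ID27-121``.

The digit codes are *functional*, not parental-origin based: ``1`` means the
late-flowering allele at every locus, even though the wild-type allele of
*BnFLC.A3b* descends from the donor parent while the wild-type alleles of
*BnFLC.A2*/*BnFLC.C2* descend from the recurrent parent.

The saturated 3-locus genetic model decomposes the 27 genotype-class means
into 27 effects (F-infinity metric): the mean ``m``, three additive effects
``a``, three dominance effects ``d``, and all two- and three-way products
(``aa``, ``ad``, ``dd``, ``aaa``, ``aad``, ``add``, ``ddd``).  Per locus the
regressors are ``x_a = -1 / +1 / 0`` and ``x_d = 0 / 0 / 1`` for states
0 / 1 / 2, so ``a`` is half the difference between homozygotes and ``d`` the
heterozygote's deviation from the homozygote midpoint.  An F2-metric
(orthogonal-contrast) coding is available through the ``metric`` switch.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOCI",
    "LocusCode",
    "NILGenotype",
    "EffectVector",
    "EFFECT_NAMES",
    "HOMOZYGOUS_EFFECT_NAMES",
    "parse_genotype_id",
    "from_digits",
    "cross",
    "design_row",
    "design_matrix",
    "all_genotypes",
    "homozygous_genotypes",
    "nil_hybrid_pedigree",
    "read_genotype_list",
    "write_genotype_list",
]

#: Fixed locus order; the digit order of every genotype ID follows it.
LOCI: tuple[str, str, str] = ("BnFLC.A2", "BnFLC.C2", "BnFLC.A3b")

_LOCUS_SHORT = ("A2", "C2", "A3")


class LocusCode(enum.IntEnum):
    """Single-locus state: mutated homozygote, wild-type homozygote, or het."""

    MUT_HOM = 0
    WT_HOM = 1
    HET = 2


class GenotypeIDError(ValueError):
    """Raised when a genotype ID string cannot be parsed."""


# Canonical ID numbering: the eight homozygotes in their published order,
# then the 19 hybrids in published order.
_CANONICAL_DIGITS: tuple[str, ...] = (
    "000", "010", "001", "100", "011", "110", "101", "111",
    "020", "002", "200", "022", "220", "202", "222", "012", "210", "021",
    "201", "120", "102", "212", "221", "122", "211", "112", "121",
)
CANONICAL_IDS: tuple[str, ...] = tuple(
    f"ID{i + 1:02d}-{digits}" for i, digits in enumerate(_CANONICAL_DIGITS)
)
_ID_BY_DIGITS: dict[str, str] = dict(zip(_CANONICAL_DIGITS, CANONICAL_IDS))


@dataclass(frozen=True, order=True)
class NILGenotype:
    """An ordered 3-locus genotype with its ID string.

    The digit suffix of ``id`` always equals ``codes`` in locus order
    (A2, C2, A3b).
    """

    id: str
    codes: tuple[LocusCode, LocusCode, LocusCode]

    def __post_init__(self) -> None:
        if len(self.codes) != 3:
            raise GenotypeIDError(f"genotype needs exactly 3 locus codes, got {self.codes!r}")
        suffix = self.id[-3:]
        if suffix != self.digits:
            raise GenotypeIDError(
                f"ID suffix {suffix!r} does not match locus codes {self.digits!r}"
            )

    @property
    def digits(self) -> str:
        return "".join(str(int(c)) for c in self.codes)

    @property
    def is_homozygous(self) -> bool:
        return LocusCode.HET not in self.codes

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id


def parse_genotype_id(id: str) -> NILGenotype:
    """Parse an ID string whose last three characters are the locus digits.

    ``"ID01-000"`` -> (MUT_HOM, MUT_HOM, MUT_HOM); ``"ID15-222"`` -> triple het.

    Raises
    ------
    GenotypeIDError
        If the suffix is shorter than three characters or contains a
        character outside ``{0, 1, 2}`` (the offending character is named).
    """
    if len(id) < 3:
        raise GenotypeIDError(f"genotype ID {id!r} too short for a 3-digit suffix")
    suffix = id[-3:]
    codes = []
    for ch in suffix:
        if ch not in "012":
            raise GenotypeIDError(
                f"genotype ID {id!r}: invalid digit {ch!r} in suffix (must be 0, 1 or 2)"
            )
        codes.append(LocusCode(int(ch)))
    return NILGenotype(id=id, codes=tuple(codes))


def from_digits(digits: str) -> NILGenotype:
    """Build a genotype from a bare 3-digit code, using the canonical ID."""
    if len(digits) != 3 or any(ch not in "012" for ch in digits):
        raise GenotypeIDError(f"invalid 3-digit genotype code {digits!r}")
    return parse_genotype_id(_ID_BY_DIGITS.get(digits, f"IDx-{digits}"))


def cross(p1: NILGenotype, p2: NILGenotype) -> NILGenotype:
    """F1 genotype of two fully homozygous parents.

    Loci where the parents agree keep that code; loci where they differ
    become heterozygous.  Heterozygous parents are rejected: the F1 of a
    non-inbred parent is not a single genotype.
    """
    for p in (p1, p2):
        if not p.is_homozygous:
            raise ValueError(f"parent {p.id} is heterozygous; cross() needs inbred parents")
    digits = "".join(
        str(int(c1)) if c1 == c2 else "2" for c1, c2 in zip(p1.codes, p2.codes)
    )
    return from_digits(digits)


# ---------------------------------------------------------------------------
# Effect vector and design matrix
# ---------------------------------------------------------------------------

def _pairs() -> list[tuple[int, int]]:
    return [(0, 1), (0, 2), (1, 2)]


def _effect_names() -> tuple[str, ...]:
    s = _LOCUS_SHORT
    names: list[str] = ["m"]
    names += [f"a_{k}" for k in s]
    names += [f"d_{k}" for k in s]
    names += [f"aa_{s[i]}{s[j]}" for i, j in _pairs()]
    # ad: ordered pairs, additive at the first index, dominance at the second
    names += [f"ad_{s[i]}{s[j]}" for i in range(3) for j in range(3) if i != j]
    names += [f"dd_{s[i]}{s[j]}" for i, j in _pairs()]
    names += ["aaa"]
    names += [f"aad_{k}" for k in s]  # dominance at the indexed locus
    names += [f"add_{k}" for k in s]  # additive at the indexed locus
    names += ["ddd"]
    return tuple(names)


#: The 27 effect names, in fixed order: m, a x3, d x3, aa x3, ad x6, dd x3,
#: aaa, aad x3, add x3, ddd.
EFFECT_NAMES: tuple[str, ...] = _effect_names()
assert len(EFFECT_NAMES) == 27

#: The 8 effects estimable from homozygous genotypes alone.
HOMOZYGOUS_EFFECT_NAMES: tuple[str, ...] = (
    "m", "a_A2", "a_C2", "a_A3", "aa_A2C2", "aa_A2A3", "aa_C2A3", "aaa",
)


@dataclass(frozen=True)
class EffectVector:
    """The 27 named components of the saturated 3-locus genetic model.

    ``values`` follows :data:`EFFECT_NAMES` order.  Trait units throughout.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 27:
            raise ValueError(f"EffectVector needs 27 components, got {len(self.values)}")

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "EffectVector":
        return cls(values=tuple(float(v) for v in arr))

    @classmethod
    def from_components(cls, **components: float) -> "EffectVector":
        """Build from named components; unnamed components default to 0."""
        unknown = set(components) - set(EFFECT_NAMES)
        if unknown:
            raise ValueError(f"unknown effect components: {sorted(unknown)}")
        return cls.from_array([components.get(name, 0.0) for name in EFFECT_NAMES])

    def __getitem__(self, name: str) -> float:
        return self.values[EFFECT_NAMES.index(name)]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(EFFECT_NAMES), dtype=float)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    # grouped views -----------------------------------------------------
    @property
    def m(self) -> float:
        return self.values[0]

    @property
    def a(self) -> tuple[float, float, float]:
        return self.values[1:4]

    @property
    def d(self) -> tuple[float, float, float]:
        return self.values[4:7]

    @property
    def aa(self) -> tuple[float, float, float]:
        return self.values[7:10]

    @property
    def ad(self) -> tuple[float, ...]:
        return self.values[10:16]

    @property
    def dd(self) -> tuple[float, float, float]:
        return self.values[16:19]

    @property
    def aaa(self) -> float:
        return self.values[19]

    @property
    def aad(self) -> tuple[float, float, float]:
        return self.values[20:23]

    @property
    def add(self) -> tuple[float, float, float]:
        return self.values[23:26]

    @property
    def ddd(self) -> float:
        return self.values[26]


def _locus_basis(code: LocusCode, metric: str) -> tuple[float, float]:
    """(x_a, x_d) regressors for one locus under the chosen metric."""
    xa = (-1.0, 1.0, 0.0)[int(code)]
    if metric == "finf":
        xd = (0.0, 0.0, 1.0)[int(code)]
    elif metric == "f2":
        xd = (-0.5, -0.5, 0.5)[int(code)]
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'finf' or 'f2'")
    return xa, xd


def design_row(g: NILGenotype, metric: str = "finf") -> np.ndarray:
    """The genotype's row of the saturated design matrix.

    Entries are the products of the per-locus (x_a, x_d) regressors matching
    :data:`EFFECT_NAMES` order; the intercept column is 1.  Under the default
    F-infinity metric all entries lie in {-1, 0, +1}.
    """
    (a1, d1), (a2, d2), (a3, d3) = (_locus_basis(c, metric) for c in g.codes)
    a = (a1, a2, a3)
    d = (d1, d2, d3)
    row = [1.0]
    row += list(a)
    row += list(d)
    row += [a[i] * a[j] for i, j in _pairs()]
    row += [a[i] * d[j] for i in range(3) for j in range(3) if i != j]
    row += [d[i] * d[j] for i, j in _pairs()]
    row += [a1 * a2 * a3]
    row += [a[i] * a[j] * d[k] for k, (i, j) in enumerate([(1, 2), (0, 2), (0, 1)])]
    row += [a[k] * d[i] * d[j] for k, (i, j) in enumerate([(1, 2), (0, 2), (0, 1)])]
    row += [d1 * d2 * d3]
    return np.asarray(row, dtype=float)


def design_matrix(
    genotypes: Sequence[NILGenotype], metric: str = "finf"
) -> pd.DataFrame:
    """Design matrix with one row per genotype (input order) and 27 columns.

    With the complete 27-genotype set the matrix is square and invertible.
    Duplicate genotypes (same digit code) and empty input are rejected.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("design_matrix needs at least one genotype")
    digits = [g.digits for g in genotypes]
    if len(set(digits)) != len(digits):
        dupes = sorted({d for d in digits if digits.count(d) > 1})
        raise ValueError(f"duplicate genotypes in design: {dupes}")
    rows = np.vstack([design_row(g, metric=metric) for g in genotypes])
    return pd.DataFrame(rows, index=[g.id for g in genotypes], columns=list(EFFECT_NAMES))


def all_genotypes() -> list[NILGenotype]:
    """All 27 genotypes in canonical ID order (8 homozygotes, 19 hybrids)."""
    return [from_digits(d) for d in _CANONICAL_DIGITS]


def homozygous_genotypes() -> list[NILGenotype]:
    """The 8 fully homozygous genotypes, ID01-000 ... ID08-111."""
    return [from_digits(d) for d in _CANONICAL_DIGITS[:8]]


def nil_hybrid_pedigree() -> list[tuple[str, str, str]]:
    """(hybrid_id, parent1_id, parent2_id) for the 19 one-plus-het hybrids.

    When more than one homozygote pair yields the same hybrid, the canonical
    pair assigns parent1 the ``0`` allele at every heterozygous locus.
    """
    pedigree = []
    for g in all_genotypes():
        if g.is_homozygous:
            continue
        p1 = "".join("0" if c == LocusCode.HET else str(int(c)) for c in g.codes)
        p2 = "".join("1" if c == LocusCode.HET else str(int(c)) for c in g.codes)
        pedigree.append((g.id, _ID_BY_DIGITS[p1], _ID_BY_DIGITS[p2]))
    return pedigree


# ---------------------------------------------------------------------------
# IO: two-column genotype lists
# ---------------------------------------------------------------------------

def read_genotype_list(path) -> list[NILGenotype]:
    """Read a two-column TSV (id, digit-code) of genotypes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "code"}.issubset(df.columns):
        raise ValueError(f"{path}: genotype list needs columns 'id' and 'code'")
    out = []
    for _, row in df.iterrows():
        g = parse_genotype_id(row["id"])
        if g.digits != row["code"]:
            raise GenotypeIDError(
                f"{path}: id {row['id']!r} disagrees with code {row['code']!r}"
            )
        out.append(g)
    return out


def write_genotype_list(genotypes: Iterable[NILGenotype], path) -> None:
    pd.DataFrame(
        [(g.id, g.digits) for g in genotypes], columns=["id", "code"]
    ).to_csv(path, sep="\t", index=False)
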