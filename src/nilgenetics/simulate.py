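"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the three kinds of input the analyses consume:

* :func:`simulate_nil_trial` -- replicated multi-environment phenotype
  trials whose genotype-class means follow a chosen 27-component effect
  vector, with Gaussian environment, plot and plant (residual) effects.
  Flowering time is emitted at plot level (it is defined per plot); all
  other traits at plant level.
* :func:`simulate_backcross_genome` -- a backcross-derived line as a mosaic
  of recurrent-parent genome with planted donor segments, observed through
  biallelic SNPs in both parents and the offspring, with an optional
  genotyping error rate.  The exact planted recurrent fraction is returned.
  Segments are planted directly rather than simulating generations of
  meiosis: the recovery algorithm only ever sees the mosaic, so this is
  sufficient and exactly controllable.
* :func:`simulate_dh_population` -- doubled haploids as single recombinant
  gametes doubled, with recombination between adjacent map positions at the
  Haldane probability ``r = (1 - exp(-2 d / 100)) / 2`` for distance ``d``
  in cM, one or more QTL, and Gaussian residual phenotypic noise.

All generators are deterministic given their parameters and seed; seeds are
explicit arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import EffectVector, all_genotypes, design_matrix
from .recovery import Call
from .trial import PLOT_LEVEL_TRAITS, TRAITS

__all__ = [
    "TrialDesign",
    "GenomeModel",
    "PopulationModel",
    "simulate_nil_trial",
    "simulate_backcross_genome",
    "simulate_dh_population",
    "qtl_effect_for_pve",
    "py_truth",
]

#: Default per-trait variance components (trait units squared): realistic
#: noise for a gram-scale yield trait and a day-scale flowering trait.
_DEFAULT_VARIANCES = {"sigma2_env": 4.0, "sigma2_plot": 1.0, "sigma2_resid": 4.0}


@dataclass(frozen=True)
class TrialDesign:
    """Replication structure of a multi-environment NIL trial.

    Defaults follow the field layout the pipeline targets: three
    environments (two winter, one spring) and five replicate plots of ten
    sampled plants each.
    """

    environments: tuple[str, ...] = ("Jiangling", "Wuhan", "Minle")
    plots_per_genotype_per_env: int = 5
    plants_per_plot: int = 10
    sigma2_env: float = _DEFAULT_VARIANCES["sigma2_env"]
    sigma2_plot: float = _DEFAULT_VARIANCES["sigma2_plot"]
    sigma2_resid: float = _DEFAULT_VARIANCES["sigma2_resid"]

    def __post_init__(self) -> None:
        if len(self.environments) < 1:
            raise ValueError("need at least one environment")
        if self.plots_per_genotype_per_env < 1 or self.plants_per_plot < 1:
            raise ValueError("replication counts must be >= 1")
        for name in ("sigma2_env", "sigma2_plot", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def py_truth(m: float = 20.0) -> EffectVector:
    """The plant-yield effect vector used as the package's reference truth.

    Additive effects 1.446 / 1.365 / 1.361 g, dominance 3.504 / 2.991 /
    3.284 g and a triple-dominance interaction of 4.393 g, all other
    interaction components zero, around an overall mean of ``m`` grams.
    """
    return EffectVector.from_components(
        m=m,
        a_A2=1.446, a_C2=1.365, a_A3=1.361,
        d_A2=3.504, d_C2=2.991, d_A3=3.284,
        ddd=4.393,
    )


def simulate_nil_trial(
    truth: Mapping[str, EffectVector],
    design: TrialDesign = TrialDesign(),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a replicated trial of all 27 NIL genotypes.

    ``truth`` maps trait label -> 27-component effect vector; genotype-class
    means are ``design_row(g) . truth``.  Per trait, each environment draws
    one common effect, each plot one effect, each plant one residual.
    Returns a long-format trial table (environment, plot, plant, genotype,
    trait, value); plot-level traits carry an empty plant field.
    """
    rng = np.random.default_rng(seed)
    genotypes = all_genotypes()
    X = design_matrix(genotypes)
    rows: list[tuple] = []
    for trait in truth:
        if trait not in TRAITS:
            raise ValueError(f"unknown trait {trait!r}")
    for trait, evec in truth.items():
        class_means = X.to_numpy() @ evec.as_array()
        plot_level = trait in PLOT_LEVEL_TRAITS
        env_effects = rng.normal(0.0, np.sqrt(design.sigma2_env), len(design.environments))
        for ei, env in enumerate(design.environments):
            for g, mean in zip(genotypes, class_means):
                for p in range(design.plots_per_genotype_per_env):
                    plot_label = f"{env}-{g.id}-p{p + 1}"
                    plot_eff = rng.normal(0.0, np.sqrt(design.sigma2_plot))
                    base = mean + env_effects[ei] + plot_eff
                    if plot_level:
                        rows.append((env, plot_label, "", g.id, trait, base))
                    else:
                        resid = rng.normal(
                            0.0, np.sqrt(design.sigma2_resid), design.plants_per_plot
                        )
                        for k in range(design.plants_per_plot):
                            rows.append(
                                (env, plot_label, f"pl{k + 1}", g.id, trait, base + resid[k])
                            )
    return pd.DataFrame(
        rows, columns=["environment", "plot", "plant", "genotype", "trait", "value"]
    )


# ---------------------------------------------------------------------------
# Backcross genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """A backcross-line genome as recurrent background plus donor segments.

    ``donor_segments`` maps chromosome -> list of (start, end, zygosity)
    with 1-based inclusive coordinates and zygosity ``"hom"`` (donor
    homozygous) or ``"het"``.  ``snp_density`` is SNPs per bp.
    """

    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"A01": 2_000_000, "A02": 2_000_000, "A03": 2_000_000}
    )
    snp_density: float = 0.005
    donor_segments: Mapping[str, Sequence[tuple[int, int, str]]] = field(
        default_factory=dict
    )
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        for chrom, segs in self.donor_segments.items():
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"donor segment on unknown chromosome {chrom!r}")
            length = self.chromosome_lengths[chrom]
            ordered = sorted(segs)
            for (s1, e1, z1), (s2, e2, z2) in zip(ordered, ordered[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping donor segments on {chrom}")
            for s, e, z in segs:
                if not (1 <= s <= e <= length):
                    raise ValueError(f"donor segment {s}-{e} outside {chrom}")
                if z not in ("hom", "het"):
                    raise ValueError(f"zygosity must be 'hom' or 'het', got {z!r}")

    @property
    def genome_length_bp(self) -> int:
        return int(sum(self.chromosome_lengths.values()))

    @property
    def recurrent_fraction(self) -> float:
        """Planted fraction of the genome that is recurrent-parent homozygous."""
        donor = sum(
            e - s + 1 for segs in self.donor_segments.values() for s, e, _ in segs
        )
        return 1.0 - donor / self.genome_length_bp


def simulate_backcross_genome(
    model: GenomeModel, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, float]:
    """SNP calls for (child, recurrent parent, donor parent).

    The parents are fixed for opposite alleles at every SNP (recurrent =
    reference homozygote, donor = alternate homozygote).  The child is
    recurrent-homozygous outside the donor segments and donor-homozygous or
    heterozygous inside them; each child call is then replaced by a random
    different call with probability ``error_rate``.  Returns the three call
    frames (chrom, pos, call) and the exact planted recurrent fraction.
    """
    rng = np.random.default_rng(seed)
    child_rows, rp_rows, dn_rows = [], [], []
    wrong = {
        Call.REF_HOM: (Call.ALT_HOM, Call.HET),
        Call.ALT_HOM: (Call.REF_HOM, Call.HET),
        Call.HET: (Call.REF_HOM, Call.ALT_HOM),
    }
    for chrom in model.chromosome_lengths:
        length = model.chromosome_lengths[chrom]
        n_snps = int(round(model.snp_density * length))
        pos = np.sort(
            rng.choice(np.arange(1, length + 1), size=min(n_snps, length), replace=False)
        )
        segs = sorted(model.donor_segments.get(chrom, ()))
        calls = np.full(pos.size, 0, dtype=int)  # 0 -> REF_HOM
        for s, e, z in segs:
            inside = (pos >= s) & (pos <= e)
            calls[inside] = 1 if z == "hom" else 2  # 1 -> ALT_HOM, 2 -> HET
        code_to_call = {0: Call.REF_HOM, 1: Call.ALT_HOM, 2: Call.HET}
        for p, c in zip(pos, calls):
            call = code_to_call[int(c)]
            if model.error_rate and rng.random() < model.error_rate:
                call = wrong[call][rng.integers(2)]
            child_rows.append((chrom, int(p), call))
            rp_rows.append((chrom, int(p), Call.REF_HOM))
            dn_rows.append((chrom, int(p), Call.ALT_HOM))
    cols = ["chrom", "pos", "call"]
    return (
        pd.DataFrame(child_rows, columns=cols),
        pd.DataFrame(rp_rows, columns=cols),
        pd.DataFrame(dn_rows, columns=cols),
        model.recurrent_fraction,
    )


# ---------------------------------------------------------------------------
# Doubled-haploid populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """A DH mapping population on a marker map with planted QTL.

    ``marker_cm`` maps chromosome -> non-decreasing marker positions (cM);
    ``qtl`` is a list of (chromosome, position_cM, additive_effect).  A DH
    individual's phenotypic contribution of a QTL is +effect for the
    donor-type allele and -effect for the recurrent-type allele.
    """

    n_individuals: int = 352
    marker_cm: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"A03": tuple(np.arange(0.0, 101.0, 5.0))}
    )
    qtl: Sequence[tuple[str, float, float]] = ()
    sigma2_resid: float = 1.0
    phenotype_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.sigma2_resid < 0:
            raise ValueError("sigma2_resid must be non-negative")
        for chrom, cm in self.marker_cm.items():
            arr = np.asarray(cm, dtype=float)
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"marker positions on {chrom} must be non-decreasing")
        for chrom, _, _ in self.qtl:
            if chrom not in self.marker_cm:
                raise ValueError(f"QTL on unknown chromosome {chrom!r}")


def haldane_r(d_cm: float) -> float:
    """Haldane recombination fraction for a map distance in centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def qtl_effect_for_pve(pve_percent: float, sigma2_resid: float) -> float:
    """Additive QTL effect (DH +-1 coding) explaining the given PVE.

    With alleles coded +-1 at frequency 1/2, the QTL contributes variance
    ``effect**2``, so ``PVE = effect**2 / (effect**2 + sigma2_resid)``.
    """
    if not 0 < pve_percent < 100:
        raise ValueError("pve_percent must be in (0, 100)")
    frac = pve_percent / 100.0
    return float(np.sqrt(frac / (1.0 - frac) * sigma2_resid))


def simulate_dh_population(
    model: PopulationModel, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Marker genotypes and phenotypes for a DH population.

    Each individual is one gamete doubled: a random phase at the first
    locus of each chromosome, then switches between adjacent loci with the
    Haldane probability for their map distance.  QTL are inserted into the
    recombination walk at their map positions and excluded from the
    returned marker frame.  Genotypes are ``A`` (recurrent-type) / ``B``
    (donor-type); phenotype = mean + sum of QTL contributions + Gaussian
    residual.
    """
    rng = np.random.default_rng(seed)
    n = model.n_individuals
    ids = [f"DH{i + 1:04d}" for i in range(n)]
    geno_cols: dict[str, np.ndarray] = {}
    qtl_geno: list[tuple[float, np.ndarray]] = []

    for chrom, cm in model.marker_cm.items():
        cm = list(map(float, cm))
        names: list[str] = []
        for pos in cm:
            name = f"{chrom}_{pos:g}"
            while name in names or name in geno_cols:
                name += "b"  # disambiguate co-located markers
            names.append(name)
        loci = [(pos, ("marker", name)) for pos, name in zip(cm, names)]
        for qchrom, qpos, qeff in model.qtl:
            if qchrom == chrom:
                loci.append((float(qpos), ("qtl", qeff)))
        loci.sort(key=lambda t: t[0])
        positions = np.array([p for p, _ in loci])
        r = haldane_r(np.diff(positions)) if len(loci) > 1 else np.zeros(0)
        # phase walk: 0 = recurrent-type, 1 = donor-type
        state = rng.integers(0, 2, size=n)
        for k, (pos, (kind, payload)) in enumerate(loci):
            if k > 0:
                switch = rng.random(n) < r[k - 1]
                state = np.where(switch, 1 - state, state)
            if kind == "marker":
                geno_cols[payload] = state.copy()
            else:
                qtl_geno.append((float(payload), state.copy()))

    genotypes = pd.DataFrame(
        {name: np.where(col == 1, "B", "A") for name, col in geno_cols.items()},
        index=ids,
    )
    pheno = np.full(n, model.phenotype_mean, dtype=float)
    for effect, state in qtl_geno:
        pheno += effect * np.where(state == 1, 1.0, -1.0)
    pheno += rng.normal(0.0, np.sqrt(model.sigma2_resid), n)
    return genotypes, pd.Series(pheno, index=ids, name="phenotype")
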