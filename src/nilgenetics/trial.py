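"""Multi-environment trial analysis: BLUEs, heritability, correlations, LSD.

Observations come from replicated field trials: each genotype is grown in
several environments, in several plots per environment, with several plants
sampled per plot.  Genotypes are fixed effects; environment, plot within
environment, and plant-within-plot (residual) are random.  The genotype
fixed-effect estimates under REML variance components are the BLUEs used by
every downstream analysis (effect decomposition, heterosis, correlations).

Flowering time (FT) is a plot-level trait -- it is scored when half the
plants of a plot have flowered -- so its model omits the plant term and its
residual is the plot-to-plot variance.  All other traits are plant-level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .reml import REMLConvergenceError, REMLResult, reml_fit

__all__ = [
    "TRAITS",
    "PLOT_LEVEL_TRAITS",
    "TrialRecord",
    "VarianceComponents",
    "records_to_frame",
    "fit_blue",
    "blue_table",
    "broad_sense_heritability",
    "pearson_matrix",
    "lsd_threshold",
    "lsd_letters",
]

#: The fixed 15-trait vocabulary with units.
TRAITS: dict[str, str] = {
    "FT": "d",        # flowering time (days to flowering)
    "BN": "",         # branch number
    "BH": "cm",       # branch height
    "PH": "cm",       # plant height
    "SH": "cm",       # stem height
    "ML": "cm",       # main raceme length
    "MSN": "",        # silique number on main raceme
    "PSN": "",        # silique number per plant
    "PY": "g",        # plant yield
    "SL": "mm",       # silique length
    "SSN": "",        # seed number per silique
    "TSW": "g",       # thousand seed weight
    "OC": "%",        # oil content
    "PC": "%",        # protein content
    "GC": "umol/g",   # glucosinolate content
}

#: Traits recorded once per plot rather than per plant.
PLOT_LEVEL_TRAITS: frozenset[str] = frozenset({"FT"})


@dataclass(frozen=True)
class TrialRecord:
    """One observation of one trait on one plant (or plot) in one environment."""

    environment: str
    plot: str
    plant: str | None
    genotype_id: str
    trait: str
    value: float

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {sorted(TRAITS)}")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.genotype_id}/{self.trait}")


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components (trait units squared) and heritability inputs."""

    sigma2_env: float
    sigma2_plot: float
    sigma2_resid: float
    sigma2_geno: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("sigma2_env", "sigma2_plot", "sigma2_resid"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


def records_to_frame(records) -> pd.DataFrame:
    """Normalise TrialRecord iterables / DataFrames to a validated DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"environment", "plot", "genotype", "trait", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        if "plant" not in df.columns:
            df["plant"] = None
    else:
        df = pd.DataFrame(
            [
                (r.environment, r.plot, r.plant, r.genotype_id, r.trait, r.value)
                for r in records
            ],
            columns=["environment", "plot", "plant", "genotype", "trait", "value"],
        )
    bad = ~df["trait"].isin(TRAITS)
    if bad.any():
        labels = sorted(df.loc[bad, "trait"].unique())
        raise ValueError(f"unknown trait labels in trial table: {labels}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if not np.isfinite(df["value"]).all():
        raise ValueError("trial table contains non-finite values")
    return df


def fit_blue(
    records,
    trait: str,
    estimate_genotype_variance: bool = True,
) -> tuple[pd.Series, VarianceComponents]:
    """Genotype BLUEs and REML variance components for one trait.

    The fixed-effect design is the genotype cell-means coding (one column
    per genotype, no intercept), so the GLS coefficients are the BLUEs
    directly.  For a perfectly balanced design each BLUE equals the
    unweighted mean of the genotype's environment means.

    ``estimate_genotype_variance`` additionally fits the genotype-random
    companion model (intercept fixed) to obtain ``sigma2_geno`` for
    broad-sense heritability; switch it off to halve the cost when only
    BLUEs are needed.
    """
    df = records_to_frame(records)
    df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    genos = np.sort(df["genotype"].unique())
    plot_level = trait in PLOT_LEVEL_TRAITS
    if plot_level:
        # one record per plot; collapse duplicates defensively
        df = (
            df.groupby(["environment", "plot", "genotype"], as_index=False)["value"].mean()
        )

    y = df["value"].to_numpy(float)
    geno_codes = pd.Categorical(df["genotype"], categories=genos).codes
    X = np.zeros((len(df), len(genos)))
    X[np.arange(len(df)), geno_codes] = 1.0
    if (X.sum(axis=0) == 0).any():
        absent = [g for g, c in zip(genos, X.sum(axis=0)) if c == 0]
        raise ValueError(f"genotypes absent from all environments: {absent}")
    env = df["environment"].to_numpy(str)
    if np.unique(env).size < 2:
        raise ValueError("fit_blue needs records from at least 2 environments")
    plot_uid = (
        df["environment"].astype(str)
        + "//" + df["genotype"].astype(str)
        + "//" + df["plot"].astype(str)
    ).to_numpy(str)

    if plot_level:
        random = {"environment": env}
    else:
        random = {"environment": env, "plot": plot_uid}

    fit = reml_fit(y, X, random, beta_names=list(genos))
    blues = pd.Series(fit.beta, index=list(genos), name=trait, dtype=float)

    sigma2_env = fit.varcomp.get("environment", 0.0)
    if plot_level:
        sigma2_plot = fit.sigma2_resid
        sigma2_resid = 0.0
    else:
        sigma2_plot = fit.varcomp.get("plot", 0.0)
        sigma2_resid = fit.sigma2_resid

    sigma2_geno = float("nan")
    if estimate_genotype_variance:
        rand_g = dict(random)
        rand_g["genotype"] = df["genotype"].to_numpy(str)
        fit_g = reml_fit(y, np.ones((len(df), 1)), rand_g, beta_names=["intercept"])
        sigma2_geno = fit_g.varcomp.get("genotype", 0.0)

    vc = VarianceComponents(
        sigma2_env=max(sigma2_env, 0.0),
        sigma2_plot=max(sigma2_plot, 0.0),
        sigma2_resid=max(sigma2_resid, 0.0),
        sigma2_geno=sigma2_geno,
    )
    return blues, vc


def blue_table(records, traits: Sequence[str] | None = None, **kwargs) -> pd.DataFrame:
    """BLUEs for several traits as a genotype x trait DataFrame."""
    df = records_to_frame(records)
    traits = list(traits) if traits is not None else sorted(df["trait"].unique())
    cols = {}
    for trait in traits:
        blues, _ = fit_blue(df, trait, **kwargs)
        cols[trait] = blues
    return pd.DataFrame(cols)


def broad_sense_heritability(vc: VarianceComponents, n_env: int, n_reps: int) -> float:
    """Entry-mean broad-sense heritability.

    ``H2 = sigma2_g / (sigma2_g + sigma2_plot / n_env + sigma2_resid / (n_env * n_reps))``,
    clipped to [0, 1].  ``n_reps`` is the number of replicate plots per
    environment (for plant-level traits multiply by plants per plot as
    appropriate to the chosen entry basis).
    """
    if n_env <= 0 or n_reps <= 0:
        raise ValueError("n_env and n_reps must be positive")
    sg = vc.sigma2_geno
    if not np.isfinite(sg):
        raise ValueError("sigma2_geno was not estimated (refit with genotype variance)")
    denom = sg + vc.sigma2_plot / n_env + vc.sigma2_resid / (n_env * n_reps)
    if denom == 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return float(np.clip(sg / denom, 0.0, 1.0))


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between traits across genotype BLUEs.

    ``table`` is genotype x trait.  Zero-variance traits yield NaN entries
    and a warning -- they are flagged, never silently set to 0.
    """
    if table.shape[0] < 3:
        raise ValueError("pearson_matrix needs at least 3 genotypes")
    sd = table.std(ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(
            f"zero-variance traits in correlation matrix: {degenerate}", stacklevel=2
        )
    corr = table.corr(method="pearson")
    for t in degenerate:
        corr.loc[t, :] = np.nan
        corr.loc[:, t] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    for t in degenerate:
        corr.loc[t, t] = np.nan
    return corr


def lsd_threshold(mse: float, df_error: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """Fisher's least significant difference for comparing two means."""
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = scipy.stats.t.ppf(1 - alpha / 2, df_error)
    return float(t * np.sqrt(2.0 * mse / n_per_mean))


def lsd_letters(
    means: pd.Series | Mapping[str, float],
    mse: float,
    df_error: int,
    n_per_mean: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from LSD all-pairwise comparisons.

    Two genotypes share a letter iff their means differ by less than the
    LSD.  The means are sorted ascending (so the smallest mean carries
    "a", matching the convention of field-trial tables), covered by maximal
    runs of mutual non-significance, and each maximal run receives one
    letter.  Ties are broken by genotype ID.
    """
    if isinstance(means, Mapping):
        means = pd.Series(means, dtype=float)
    lsd = lsd_threshold(mse, df_error, n_per_mean, alpha)
    order = sorted(means.index, key=lambda g: (means[g], str(g)))
    vals = [means[g] for g in order]
    n = len(order)
    # maximal intervals [i, j] with vals[j] - vals[i] < lsd; since the
    # right endpoint j(i) is non-decreasing in i, an interval is maximal
    # iff it extends the previous right endpoint
    maximal: list[tuple[int, int]] = []
    last_j = -1
    for i in range(n):
        j = i
        while j + 1 < n and vals[j + 1] - vals[i] < lsd:
            j += 1
        if j > last_j or not maximal:
            maximal.append((i, j))
            last_j = j
    letters = {g: "" for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for k, (i, j) in enumerate(maximal):
        letter = alphabet[k % 26] * (k // 26 + 1)
        for idx in range(i, j + 1):
            letters[order[idx]] += letter
    return letters
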