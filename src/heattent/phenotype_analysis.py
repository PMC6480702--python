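"""Phenotype formulas and trial summaries for an HNT stress experiment.

Implements the chlorophyll-fluorescence quantities used to phenotype
photosynthetic capacity —

    QY  = (FM′ − Ft) / FM′          effective quantum yield of PSII
    ETR = QY · PAR · 0.84 · 0.5     electron transport rate

(0.84 is the approximate fraction of incident light absorbed by the
leaf, 0.5 the PSII:PSI partitioning) — plus summary statistics for a
genotype × treatment × replicate yield trial: per-genotype means ± SE,
percent yield reduction under stress, a within-genotype permutation test
for the treatment effect, and a seeded synthetic trial generator that
emulates a 12-genotype winter-wheat experiment with ~20% mean yield loss
under high night-time temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, IncompleteDesignError

__all__ = [
    "FluorescenceReading",
    "quantum_yield",
    "etr",
    "percent_reduction",
    "validate_trial",
    "summarize_trial",
    "TrialSummary",
    "permutation_treatment_test",
    "generate_synthetic_trial",
]

LIGHT_ABSORPTANCE = 0.84
PSII_FRACTION = 0.5

CONTROL = "control"
TREATMENT = "hnt"


@dataclass(frozen=True)
class FluorescenceReading:
    """One light-adapted fluorometer reading.

    ``fm_prime`` is the maximal fluorescence yield under a saturating
    pulse, ``ft`` the steady-state yield under ambient light (relative
    units), and ``par`` the photosynthetically active radiation at the
    leaf in µmol photons m⁻² s⁻¹.
    """

    fm_prime: float
    ft: float
    par: float = 0.0

    def __post_init__(self) -> None:
        if self.fm_prime <= 0:
            raise DomainError(f"fm_prime must be positive, got {self.fm_prime}")
        if not 0 <= self.ft <= self.fm_prime:
            raise DomainError(f"ft must be in [0, fm_prime], got {self.ft}")
        if self.par < 0:
            raise DomainError(f"par must be non-negative, got {self.par}")


def quantum_yield(reading: FluorescenceReading) -> float:
    """Effective quantum yield of PSII, ΔF/FM′ = (FM′ − Ft)/FM′ ∈ [0, 1]."""
    return (reading.fm_prime - reading.ft) / reading.fm_prime


def etr(qy: float, par: float) -> float:
    """Electron transport rate QY · PAR · 0.84 · 0.5, µmol electrons m⁻² s⁻¹."""
    if not 0 <= qy <= 1:
        raise DomainError(f"qy must be in [0, 1], got {qy}")
    if par < 0:
        raise DomainError(f"par must be non-negative, got {par}")
    return qy * par * LIGHT_ABSORPTANCE * PSII_FRACTION


def percent_reduction(control_mean: float, treatment_mean: float) -> float:
    """Percent reduction of a treatment mean relative to control.

    Negative values report an increase under treatment.
    """
    if control_mean <= 0:
        raise DomainError(f"control_mean must be positive, got {control_mean}")
    return 100.0 * (control_mean - treatment_mean) / control_mean


def validate_trial(table: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy trial table and return it with canonical dtypes.

    Expects columns ``genotype``, ``treatment`` (control/hnt), ``rep``
    and ``yield_g_m2``; every genotype must carry both treatment arms.
    """
    required = {"genotype", "treatment", "rep", "yield_g_m2"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"trial table missing columns: {sorted(missing)}")
    bad = set(table["treatment"].unique()) - {CONTROL, TREATMENT}
    if bad:
        raise ConfigError(f"unknown treatment labels: {sorted(bad)}")
    if (table["yield_g_m2"] <= 0).any():
        raise DomainError("yields must be positive")
    arms = table.groupby("genotype")["treatment"].agg(lambda s: set(s))
    offenders = [g for g, a in arms.items() if a != {CONTROL, TREATMENT}]
    if offenders:
        raise IncompleteDesignError(offenders)
    return table


@dataclass
class TrialSummary:
    """Per-genotype and grand-mean results of a yield trial."""

    per_genotype: pd.DataFrame
    """Columns: control_mean, control_se, hnt_mean, hnt_se, n_control,
    n_hnt, reduction_pct."""

    mean_reduction_pct: float
    """Unweighted mean of per-genotype percent reductions."""

    pooled_reduction_pct: float
    """Percent reduction of the pooled treatment mean vs pooled control."""


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0


def summarize_trial(table: pd.DataFrame) -> TrialSummary:
    """Per-genotype means ± SE per treatment and percent reductions.

    The grand reduction is reported two ways: as the unweighted mean of
    per-genotype reductions and as the reduction of pooled means; the two
    differ when control means vary across genotypes.
    """
    table = validate_trial(table)
    rows = {}
    for genotype, sub in table.groupby("genotype", sort=True):
        c = sub.loc[sub["treatment"] == CONTROL, "yield_g_m2"].to_numpy()
        t = sub.loc[sub["treatment"] == TREATMENT, "yield_g_m2"].to_numpy()
        rows[genotype] = {
            "control_mean": c.mean(),
            "control_se": _se(c),
            "hnt_mean": t.mean(),
            "hnt_se": _se(t),
            "n_control": len(c),
            "n_hnt": len(t),
            "reduction_pct": percent_reduction(c.mean(), t.mean()),
        }
    per_genotype = pd.DataFrame.from_dict(rows, orient="index")
    per_genotype.index.name = "genotype"

    pooled_c = table.loc[table["treatment"] == CONTROL, "yield_g_m2"].mean()
    pooled_t = table.loc[table["treatment"] == TREATMENT, "yield_g_m2"].mean()
    return TrialSummary(
        per_genotype=per_genotype,
        mean_reduction_pct=float(per_genotype["reduction_pct"].mean()),
        pooled_reduction_pct=percent_reduction(pooled_c, pooled_t),
    )


def _paired_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Control / treatment yields as (genotype, rep) arrays; requires a
    balanced paired layout within each genotype."""
    piv_c = table[table["treatment"] == CONTROL].pivot_table(
        index="genotype", columns="rep", values="yield_g_m2")
    piv_t = table[table["treatment"] == TREATMENT].pivot_table(
        index="genotype", columns="rep", values="yield_g_m2")
    piv_t = piv_t.reindex(index=piv_c.index, columns=piv_c.columns)
    c, t = piv_c.to_numpy(), piv_t.to_numpy()
    if np.isnan(c).any() or np.isnan(t).any():
        raise ConfigError("permutation test requires a balanced paired design")
    return c, t


def _mean_reduction(control: np.ndarray, treatment: np.ndarray) -> np.ndarray:
    """Unweighted mean per-genotype percent reduction.

    Accepts arrays of shape (..., genotype, rep) so permuted replicates
    broadcast through in one vectorized pass.
    """
    cm = control.mean(axis=-1)
    tm = treatment.mean(axis=-1)
    return (100.0 * (cm - tm) / cm).mean(axis=-1)


def permutation_treatment_test(
    table: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for a nonzero mean yield reduction.

    Treatment labels are permuted within each genotype × replicate block
    (i.e. the control/stress labels of each paired plot are swapped at
    random), the unweighted mean per-genotype percent reduction is
    recomputed for every permutation, and

        p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ConfigError(f"n_perm must be >= 99, got {n_perm}")
    control, treatment = _paired_arrays(validate_trial(table))
    obs = float(_mean_reduction(control, treatment))

    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm,) + control.shape) < 0.5
    c_perm = np.where(swap, treatment, control)
    t_perm = np.where(swap, control, treatment)
    stats = _mean_reduction(c_perm, t_perm)
    return float((1 + np.sum(np.abs(stats) >= abs(obs) - 1e-12)) / (n_perm + 1))


def generate_synthetic_trial(
    seed: int,
    n_genotypes: int = 12,
    reps: int = 3,
    control_mean_range: tuple[float, float] = (250.0, 450.0),
    mean_reduction_pct: float = 20.3,
    reduction_range: tuple[float, float] = (6.9, 41.4),
    noise_cv: float = 0.1,
    etr_flag_reduction_range: tuple[float, float] = (0.5, 14.3),
    etr_spike_reduction_range: tuple[float, float] = (5.7, 19.4),
    etr_mean_range: tuple[float, float] = (120.0, 220.0),
) -> pd.DataFrame:
    """Seeded synthetic genotype × treatment × replicate trial table.

    Per-genotype control yield means are drawn uniformly from
    ``control_mean_range`` (g/m²).  True percent reductions span
    ``reduction_range``: the extremes are assigned to two genotypes and
    the rest are Beta-distributed within the range with the expectation
    pinned so the population mean reduction equals ``mean_reduction_pct``
    exactly.  Replicate noise is log-normal with coefficient of variation
    ``noise_cv`` and unit mean, so yields stay positive and expectations
    are unbiased.  Flag-leaf and spike ETR columns follow the same recipe
    with their own reduction ranges.
    """
    low, high = reduction_range
    if not (low <= mean_reduction_pct <= high):
        raise ConfigError(
            f"mean_reduction_pct {mean_reduction_pct} outside reduction range {reduction_range}")
    if noise_cv < 0:
        raise ConfigError("noise_cv must be non-negative")
    if n_genotypes < 2:
        raise ConfigError("need at least 2 genotypes")

    rng = np.random.default_rng(seed)
    genotypes = [f"G{i+1:02d}" for i in range(n_genotypes)]
    control_means = rng.uniform(*control_mean_range, size=n_genotypes)
    reductions = _spanning_reductions(rng, n_genotypes, mean_reduction_pct, low, high)
    etr_flag_means = rng.uniform(*etr_mean_range, size=n_genotypes)
    etr_spike_means = rng.uniform(*etr_mean_range, size=n_genotypes)
    etr_flag_red = rng.uniform(*etr_flag_reduction_range, size=n_genotypes)
    etr_spike_red = rng.uniform(*etr_spike_reduction_range, size=n_genotypes)

    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean log-normal

        def noise(size):
            return rng.lognormal(mu, sigma, size=size)
    else:
        def noise(size):
            return np.ones(size)

    rows = []
    for g in range(n_genotypes):
        for treatment, factor in ((CONTROL, 1.0), (TREATMENT, 1.0 - reductions[g] / 100.0)):
            f_flag = 1.0 if treatment == CONTROL else 1.0 - etr_flag_red[g] / 100.0
            f_spike = 1.0 if treatment == CONTROL else 1.0 - etr_spike_red[g] / 100.0
            y = control_means[g] * factor * noise(reps)
            ef = etr_flag_means[g] * f_flag * noise(reps)
            es = etr_spike_means[g] * f_spike * noise(reps)
            for r in range(reps):
                rows.append((genotypes[g], treatment, r + 1, y[r], ef[r], es[r]))
    return pd.DataFrame(
        rows, columns=["genotype", "treatment", "rep", "yield_g_m2",
                       "etr_flag", "etr_spike"])


def _spanning_reductions(
    rng: np.random.Generator, n: int, mean: float, low: float, high: float
) -> np.ndarray:
    """Per-genotype true reductions spanning [low, high] with the given mean.

    Two genotypes receive the range endpoints; the remainder are drawn
    from a Beta distribution over the range whose expectation makes the
    population mean equal ``mean``.  Genotype assignment is shuffled.
    """
    if high == low:
        return np.full(n, low)
    r = np.empty(n)
    r[0], r[1] = low, high
    if n > 2:
        mid_mean = (n * mean - low - high) / (n - 2)
        if not (low <= mid_mean <= high):
            raise ConfigError(
                f"mean {mean} not attainable inside range ({low}, {high}) with n={n}")
        rel = (mid_mean - low) / (high - low)
        concentration = 4.0
        a = max(rel * concentration, 1e-6)
        b = max((1.0 - rel) * concentration, 1e-6)
        r[2:] = low + (high - low) * rng.beta(a, b, size=n - 2)
    return r[rng.permutation(n)]
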