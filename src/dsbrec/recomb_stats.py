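"""Frequency, rate, survival and comparison statistics for plating assays.

Covers the colony-count arithmetic of recombination plating (recombinants per
survivor, net induced frequency, induction efficiency per krad), fluctuation
analysis of spontaneous rates by the Lea-Coulson method of the median, summary
two-sample t tests, and dose-modifying factors from survival curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FrequencyRecord",
    "FrequencyEstimate",
    "NetFrequency",
    "FluctuationAssay",
    "RateEstimate",
    "SurvivalCurve",
    "TTestResult",
    "frequency",
    "net_frequency",
    "induction_efficiency",
    "lea_coulson_m",
    "median_rate",
    "summary_t_test",
    "dose_modifying_factor",
    "survival_from_counts",
]

#: Lea-Coulson median-equation constant: the median mutant count r0 of a
#: Luria-Delbrück distribution with mean mutation number m satisfies
#: r0/m - ln(m) = 1.24.
LEA_COULSON_CONSTANT = 1.24


# ---------------------------------------------------------------------------
# Recombinant frequencies (per survivor)
# ---------------------------------------------------------------------------

@dataclass
class FrequencyRecord:
    """One plating observation: selective and complete-medium colony counts.

    Dilution factors are the fold-dilution applied before plating, so the
    number of viable cells represented by one colony is ``dilution``.
    """

    strain: str
    selective_colonies: float
    selective_cells_plated: float
    total_colonies: float
    total_cells_plated: float
    selective_dilution: float = 1.0
    total_dilution: float = 1.0
    agent: str = "IR"
    dose: float = 0.0
    dose_units: str = "krad"

    def __post_init__(self):
        if min(self.selective_colonies, self.total_colonies) < 0:
            raise ValueError("colony counts must be non-negative")
        if min(self.selective_cells_plated, self.total_cells_plated) <= 0:
            raise ValueError("cells plated must be positive")


@dataclass
class FrequencyEstimate:
    """Recombinants per survivor, with a detection bound when the count is 0."""

    value: float
    n_selective: int
    plating_efficiency: float
    resolution_bound: float | None = None

    def __float__(self) -> float:
        return self.value


def frequency(record: FrequencyRecord) -> FrequencyEstimate:
    """Recombinants per *viable* cell (per survivor).

    (selective colonies / selective cells plated) corrected by the plating
    efficiency on complete medium, each count scaled by its dilution factor.
    Zero selective colonies yield 0 with the assay's resolution bound
    (one colony's worth) reported alongside.
    """
    if record.total_colonies <= 0:
        raise ValueError("zero colonies on complete medium: survival undefined")
    plating_eff = (record.total_colonies * record.total_dilution
                   / record.total_cells_plated)
    per_plated = (record.selective_colonies * record.selective_dilution
                  / record.selective_cells_plated)
    value = per_plated / plating_eff
    bound = None
    if record.selective_colonies == 0:
        bound = (record.selective_dilution / record.selective_cells_plated
                 / plating_eff)
    return FrequencyEstimate(value=value, n_selective=int(record.selective_colonies),
                             plating_efficiency=plating_eff, resolution_bound=bound)


@dataclass
class NetFrequency:
    """Induced-minus-spontaneous frequency; negatives kept but flagged."""

    value: float
    negative: bool

    def __float__(self) -> float:
        return self.value


def net_frequency(treated, untreated) -> NetFrequency:
    """Net recombination frequency: treated minus the no-treatment frequency.

    Negative differences (possible at sub-inducing doses by sampling noise)
    are reported as-is with a flag so downstream display may zero-clamp
    without biasing averages.
    """
    value = float(treated) - float(untreated)
    return NetFrequency(value=value, negative=value < 0)


def induction_efficiency(points) -> float:
    """Recombinants per survivor per unit dose: through-origin slope.

    ``points`` is an iterable of (dose, net_frequency); the origin (no dose,
    no net induction) is implicit in the through-origin constraint.
    """
    pts = [(float(d), float(f)) for d, f in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 dose points")
    d = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("all doses are zero")
    return float(d @ f / denom)


# ---------------------------------------------------------------------------
# Fluctuation analysis (method of the median)
# ---------------------------------------------------------------------------

@dataclass
class FluctuationAssay:
    """Mutant counts from parallel cultures grown to a common final size."""

    counts: np.ndarray
    cells_per_culture: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("mutant counts must be non-negative")
        if self.cells_per_culture <= 0:
            raise ValueError("cells per culture must be positive")

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass
class RateEstimate:
    rate: float  # mutations per cell per division
    ci_low: float
    ci_high: float
    m: float  # mean mutations per culture
    n_cultures: int
    method: str = "lea_coulson_median"
    ci_method: str = "percentile_bootstrap"
    below_resolution: bool = False


def lea_coulson_m(median_count: float) -> float:
    """Solve r0/m - ln(m) = 1.24 for the mean mutation number m.

    The left-hand side is strictly decreasing in m, so the root is unique;
    it is bracketed and found with Brent's method.
    """
    if median_count <= 0:
        raise ValueError("median mutant count must be positive")
    r0 = float(median_count)

    def f(m):
        return r0 / m - math.log(m) - LEA_COULSON_CONSTANT

    lo, hi = 1e-12, 1.0
    while f(hi) > 0:
        hi *= 10
        if hi > 1e12:
            raise RuntimeError("no root in bracket")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def _rates_from_medians(medians: np.ndarray, cells: float) -> np.ndarray:
    """Vector of rate estimates; root-solve once per unique median value."""
    uniq = np.unique(medians)
    table = {}
    for r0 in uniq:
        table[r0] = lea_coulson_m(r0) / cells if r0 > 0 else 0.0
    return np.array([table[r0] for r0 in medians])


def median_rate(assay: FluctuationAssay, *, n_boot: int = 10_000,
                conf: float = 0.95, seed: int = 0) -> RateEstimate:
    """Mutation (recombination) rate by the Lea-Coulson method of the median.

    The median mutant count across parallel cultures determines the mean
    mutation number m per culture via r0/m - ln(m) = 1.24; the rate per cell
    per division is m divided by the final cells per culture.  The confidence
    interval is a seeded nonparametric percentile bootstrap over cultures.

    A zero median means the rate is below the assay's resolution; the point
    estimate is reported as 0 with an upper bound from the fraction of
    mutant-free cultures (p0 method).
    """
    counts = np.asarray(assay.counts)
    if len(counts) < 5:
        raise ValueError("need at least 5 cultures for rate estimation")
    cells = assay.cells_per_culture
    med = float(np.median(counts))
    if med <= 0:
        p0 = max((counts == 0).mean(), 1.0 / (2 * len(counts)))
        upper = -math.log(p0) / cells if p0 < 1 else lea_coulson_m(0.5) / cells
        return RateEstimate(rate=0.0, ci_low=0.0, ci_high=upper,
                            m=0.0, n_cultures=len(counts),
                            ci_method="p0_upper_bound", below_resolution=True)
    m = lea_coulson_m(med)
    rate = m / cells
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(counts), size=(n_boot, len(counts)))
    boot_medians = np.median(counts[idx], axis=1)
    boot_rates = _rates_from_medians(boot_medians, cells)
    alpha = (1 - conf) / 2
    lo, hi = np.quantile(boot_rates, [alpha, 1 - alpha])
    return RateEstimate(rate=rate, ci_low=float(lo), ci_high=float(hi),
                        m=m, n_cultures=len(counts))


# ---------------------------------------------------------------------------
# Summary-statistics t test
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    tails: int
    pooled: bool


def summary_t_test(mean1: float, sem1: float, n1: int,
                   mean2: float, sem2: float, n2: int,
                   *, tails: int = 2, welch: bool = False) -> TTestResult:
    """Two-sample t test from published summaries (mean ± SEM, n).

    Group SDs are recovered as SEM·sqrt(n).  The default pooled-variance test
    has df = n1 + n2 - 2 and reproduces the test on the underlying raw data
    exactly when fed that data's summaries; ``welch=True`` uses the
    Welch-Satterthwaite approximation instead.  One-tailed p assumes the
    observed direction was the predicted one.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    var1 = (sem1 * math.sqrt(n1)) ** 2
    var2 = (sem2 * math.sqrt(n2)) ** 2
    if welch:
        se2 = var1 / n1 + var2 / n2
        df = se2**2 / ((var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    t = (mean1 - mean2) / math.sqrt(se2)
    p = stats.t.sf(abs(t), df) * tails
    return TTestResult(t=t, df=float(df), p=float(p), tails=tails, pooled=not welch)


# ---------------------------------------------------------------------------
# Survival curves and dose-modifying factor
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Surviving fraction versus dose, with replicate SEMs when available."""

    doses: np.ndarray
    surviving_fraction: np.ndarray
    n_cultures: int = 1
    sem: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)
        if len(self.doses) != len(self.surviving_fraction):
            raise ValueError("doses and surviving fractions differ in length")
        if len(self.doses) < 2:
            raise ValueError("a survival curve needs at least 2 dose points")
        order = np.argsort(self.doses)
        self.doses = self.doses[order]
        self.surviving_fraction = self.surviving_fraction[order]
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)[order]
        if (self.surviving_fraction <= 0).any():
            raise ValueError("surviving fractions must be positive")
        over = self.doses[self.surviving_fraction > 1.0]
        for d in over:  # sampling noise can push S past 1; keep but flag
            self.flags.append(f"S>1 at dose {d:g}")

    def dose_at(self, level: float) -> float:
        """Dose producing the given surviving fraction, by log-linear
        interpolation between measured points."""
        if not 0 < level <= 1:
            raise ValueError("survival level must be in (0, 1]")
        logS = np.log(self.surviving_fraction)
        target = math.log(level)
        if target > logS.max() or target < logS.min():
            raise ValueError(
                f"level {level:g} outside the curve's measured range")
        # logS is (noisily) decreasing with dose; walk the segments
        for i in range(len(self.doses) - 1):
            y0, y1 = logS[i], logS[i + 1]
            if (y0 - target) * (y1 - target) <= 0:
                if y1 == y0:
                    return float(self.doses[i])
                w = (target - y0) / (y1 - y0)
                return float(self.doses[i] + w * (self.doses[i + 1] - self.doses[i]))
        raise ValueError(f"level {level:g} not bracketed by the curve")


def dose_modifying_factor(curve_a: SurvivalCurve, curve_b: SurvivalCurve,
                          level: float) -> float:
    """Ratio of doses giving equal killing: dose_A(level) / dose_B(level).

    A DMF of 2 means strain B reaches the same survival with half the dose
    strain A requires.
    """
    return curve_a.dose_at(level) / curve_b.dose_at(level)


def survival_from_counts(df: pd.DataFrame) -> SurvivalCurve:
    """Build a survival curve from tidy colony counts.

    Expects columns ``dose, replicate, cells_plated, dilution, colonies``;
    the plating efficiency at each dose, averaged over replicates, is divided
    by the dose-0 efficiency.  SEM at each dose is the replicate SEM on the
    same scale.
    """
    required = {"dose", "cells_plated", "dilution", "colonies"}
    if missing := required - set(df.columns):
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    work = df.copy()
    work["efficiency"] = work["colonies"] * work["dilution"] / work["cells_plated"]
    if not (work["dose"] == 0).any():
        raise ValueError("survival needs an unirradiated (dose 0) reference")
    eff0 = work.loc[work["dose"] == 0, "efficiency"].mean()
    if eff0 <= 0:
        raise ValueError("zero plating efficiency at dose 0")
    grouped = work.groupby("dose")["efficiency"]
    doses = np.array(sorted(grouped.groups))
    S = grouped.mean().loc[doses].to_numpy() / eff0
    sem = grouped.sem().loc[doses].to_numpy() / eff0
    n = int(grouped.count().min())
    return SurvivalCurve(doses=doses, surviving_fraction=S, n_cultures=n, sem=sem)
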