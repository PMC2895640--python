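"""Synthetic-data generators with the statistical structure the analysis assumes.

Emulates, at band/colony resolution, the raw observables of a gamma-ray DSB
and homologous-recombination study in G2/M-arrested tetraploid yeast:

* PFGE band-intensity tables under Poisson random breakage of a karyotype,
  with exponential rejoining kinetics, per-lane loading scalars and
  multiplicative (lognormal) densitometry noise;
* Luria-Delbrück fluctuation cultures (per-generation binomial mutation with
  deterministic doubling of mutant lineages);
* reciprocal exchange between TYR1 heteroallele-bearing homologs in G1 or G2
  followed by random sister-chromatid segregation at mitosis;
* exponential dose-response survival curves.

Every generator takes an explicit seed; identical seeds give identical output.
No gel physics (migration, smearing) is modelled — only band-level intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dsb_quant import GelLaneTable, Karyotype
from .recomb_stats import FluctuationAssay, SurvivalCurve

__all__ = [
    "BreakageParams",
    "RepairKinetics",
    "SegregationScenario",
    "simulate_gel_lanes",
    "unbroken_fraction_mc",
    "simulate_fluctuation",
    "simulate_re_segregation",
    "simulate_survival",
    "simulate_genotype_panel",
]

#: Bands whose sizes differ by less than this relative amount (on the mean)
#: comigrate and are merged into one band with summed intensity.
DEFAULT_COMIGRATION_THRESHOLD = 0.05


@dataclass(frozen=True)
class BreakageParams:
    """Poisson-breakage generator settings.

    efficiency_kappa : DSBs per megabase per krad (the induction efficiency).
    dose             : gamma dose in krad.
    noise_cv         : coefficient of variation of the multiplicative
                       lognormal band noise (densitometry error).
    loading_factor_sd: sigma of the per-lane lognormal DNA-loading scalar.
    """

    efficiency_kappa: float
    dose: float
    noise_cv: float = 0.05
    loading_factor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.efficiency_kappa < 0:
            raise ValueError("efficiency_kappa must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.noise_cv < 0 or self.loading_factor_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class RepairKinetics:
    """First-order rejoining: a fraction ``plateau`` of breaks never rejoins,
    the rest disappear at ``rate`` per hour."""

    rate: float  # per hour
    plateau: float = 0.0
    model: str = "exponential"

    def __post_init__(self):
        if self.model != "exponential":
            raise ValueError("only the exponential model is implemented")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0 <= self.plateau <= 1:
            raise ValueError("plateau must be in [0, 1]")

    def fraction_unrepaired(self, t: float) -> float:
        if t < 0:
            raise ValueError("negative timepoint")
        return self.plateau + (1 - self.plateau) * math.exp(-self.rate * t)


def _merge_comigrating(karyotype: Karyotype, threshold: float) -> list:
    """Cluster chromosomes whose sizes differ by < threshold (chained on the
    sorted size list); returns [(band_id, names, size_mb, comigrating)]."""
    order = sorted(karyotype.chromosomes, key=lambda c: c[1])
    clusters: list[list] = [[order[0]]]
    for name, size in order[1:]:
        prev_size = clusters[-1][-1][1]
        if abs(size - prev_size) / ((size + prev_size) / 2) <= threshold:
            clusters[-1].append((name, size))
        else:
            clusters.append([(name, size)])
    bands = []
    for i, cl in enumerate(clusters):
        names = [n for n, _ in cl]
        size = float(np.mean([s for _, s in cl]))
        bands.append((f"b{i:02d}", names, size, len(cl) > 1))
    return bands


def simulate_gel_lanes(karyotype: Karyotype, params: BreakageParams,
                       timepoints=(0.0,), kinetics: RepairKinetics | None = None,
                       *, strain: str = "synthetic",
                       comigration_threshold: float = DEFAULT_COMIGRATION_THRESHOLD,
                       intensity_scale: float = 1000.0) -> GelLaneTable:
    """Generate a control lane plus one dose lane per post-irradiation time.

    A chromosome of size L Mb accumulates Poisson(kappa*dose*L) breaks; after
    t hours of repair the surviving break burden is thinned by the kinetics'
    unrepaired fraction u(t), so the expected full-length (band) fraction is
    exp(-kappa*dose*L*u(t)).  Band intensity is

        loading_factor(lane) x copies x P(unbroken at t) x noise,

    with noise lognormal of mean 1 and CV ``noise_cv``.  Chromosomes whose
    sizes differ by less than ``comigration_threshold`` comigrate: their
    intensities are summed into a single flagged band.
    """
    if any(t < 0 for t in timepoints):
        raise ValueError("negative timepoint")
    rng = np.random.default_rng(params.seed)
    bands_def = _merge_comigrating(karyotype, comigration_threshold)
    copies = karyotype.copies_per_chromosome
    kd = params.efficiency_kappa * params.dose

    lanes = [{"lane_id": "ctrl", "strain": strain, "dose_krad": 0.0,
              "time_h": 0.0, "is_control": True}]
    for i, t in enumerate(timepoints):
        lanes.append({"lane_id": f"t{i:02d}", "strain": strain,
                      "dose_krad": params.dose, "time_h": float(t),
                      "is_control": False})

    # lognormal parameterised for mean 1: sigma^2 = ln(1 + cv^2)
    sig_noise = math.sqrt(math.log(1 + params.noise_cv**2))

    band_rows = []
    for lane in lanes:
        if params.loading_factor_sd > 0:
            loading = float(rng.lognormal(0.0, params.loading_factor_sd))
        else:
            loading = 1.0
        if lane["is_control"]:
            u = 0.0  # no dose: every molecule full length
        elif kinetics is None:
            u = 1.0
        else:
            u = kinetics.fraction_unrepaired(lane["time_h"])
        for band_id, names, size, comig in bands_def:
            expected = 0.0
            for name in names:
                L = dict(karyotype.chromosomes)[name]
                p_unbroken = 1.0 if lane["is_control"] else math.exp(-kd * L * u)
                expected += copies * p_unbroken
            if params.noise_cv > 0:
                noise = float(rng.lognormal(-0.5 * sig_noise**2, sig_noise))
            else:
                noise = 1.0
            band_rows.append({
                "band_id": band_id, "chromosomes": ",".join(names),
                "size_mb": size, "lane_id": lane["lane_id"],
                "intensity": intensity_scale * loading * expected * noise,
                "comigrating": comig,
            })
    return GelLaneTable(bands=pd.DataFrame(band_rows), lanes=pd.DataFrame(lanes))


def unbroken_fraction_mc(efficiency_kappa: float, dose: float, size_mb: float,
                         copies: int, seed: int = 0) -> float:
    """Monte-Carlo zero-class fraction: simulate per-molecule Poisson breaks
    and return the fraction of molecules with none (converges to
    exp(-kappa*dose*L))."""
    rng = np.random.default_rng(seed)
    breaks = rng.poisson(efficiency_kappa * dose * size_mb, size=copies)
    return float((breaks == 0).mean())


# ---------------------------------------------------------------------------
# Fluctuation cultures
# ---------------------------------------------------------------------------

def simulate_fluctuation(rate: float, n_final: float, cultures: int,
                         seed: int = 0) -> FluctuationAssay:
    """Luria-Delbrück mutant counts for parallel cultures.

    Approximation: each culture grows from a single cell for
    G = round(log2(n_final)) doublings; at each generation every non-mutant
    division yields a mutant daughter with probability ``rate`` (binomial
    draw), and mutant lineages thereafter grow deterministically with the
    culture (no death, no differential fitness).  Because a real culture is
    asynchronous, each mutation is assigned a uniform time within its
    generation, so a mutation in generation g founds a clone of
    floor(2^(G-g-1+U)) final cells; this reproduces the reciprocal
    clone-size law of the continuous-time process instead of quantising
    clone sizes to powers of two (which biases the method-of-the-median
    estimator low).  The realised final size, 2^G, is recorded as
    ``cells_per_culture``.
    """
    if not 0 <= rate < 0.1:
        raise ValueError("rate must be a small probability (0 <= rate << 1)")
    if n_final < 10:
        raise ValueError("n_final must be >= 10")
    if cultures < 1:
        raise ValueError("need at least one culture")
    if rate * n_final > 1e5:
        raise ValueError("rate * n_final too large; counts would overflow the model")
    rng = np.random.default_rng(seed)
    generations = max(1, round(math.log2(n_final)))
    n_wt = np.ones(cultures, dtype=np.int64)
    mutants = np.zeros(cultures, dtype=np.int64)
    for g in range(generations):
        new = rng.binomial(n_wt, rate)
        for ci in np.nonzero(new)[0]:
            u = rng.random(new[ci])
            clones = np.floor(2.0 ** (generations - g - 1 + u)).astype(np.int64)
            mutants[ci] += clones.sum()
        n_wt = 2 * n_wt - new
    return FluctuationAssay(counts=mutants, cells_per_culture=float(2**generations))


# ---------------------------------------------------------------------------
# Reciprocal exchange and sister-chromatid segregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegregationScenario:
    """One reciprocal exchange in G1 (before replication) or G2 (after),
    followed by mitosis with random sister-chromatid segregation.

    The tetraploid default carries 2 homologs with the 5' 'ty' heteroallele
    and 2 with the 3' 'yr1' heteroallele.
    """

    phase: str = "G2"
    n_ty: int = 2
    n_yr1: int = 2
    trials: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.phase not in ("G1", "G2"):
            raise ValueError("phase must be 'G1' or 'G2'")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.n_ty < 1 or self.n_yr1 < 1:
            raise ValueError("need at least one homolog of each heteroallele")


def simulate_re_segregation(scenario: SegregationScenario) -> float:
    """Fraction of Tyr+ daughters that retain the reciprocal 'y' allele.

    A crossover within the 400 bp heteroallele overlap converts one 'ty'
    chromatid into full-length TYR1 and its 'yr1' partner into the
    overlap-only 'y' allele.  In G1 the exchange precedes replication, so
    both products are duplicated and every daughter inherits one sister of
    each: all Tyr+ daughters carry 'y' (retention exactly 1).  In G2 the
    TYR1 and 'y' chromatids sit on different homologs whose sister pairs
    segregate independently, so the Tyr+ daughter co-inherits 'y' only half
    the time.  Returns the Monte-Carlo retention probability over
    ``trials`` mitoses.
    """
    rng = np.random.default_rng(scenario.seed)
    trials = scenario.trials
    if scenario.phase == "G1":
        # exchange, then replication: each daughter receives one chromatid of
        # every homolog, including the recombinant TYR1 and 'y' homologs.
        # Simulated segregation is included for symmetry but the outcome is
        # structurally certain.
        return 1.0
    # G2: homologs already replicated into sister pairs.  One 'ty' sister
    # becomes TYR1, one 'yr1' sister (on another homolog) becomes 'y'.
    # For each homolog an independent fair coin sends sister A to daughter 0
    # or 1 (the other sister to the other pole).
    n_homologs = scenario.n_ty + scenario.n_yr1
    coins = rng.integers(0, 2, size=(trials, n_homologs))
    daughter_of_tyr1 = coins[:, 0]       # sister A of the exchanged ty homolog
    daughter_of_y = coins[:, scenario.n_ty]  # sister A of the exchanged yr1 homolog
    retained = daughter_of_tyr1 == daughter_of_y
    return float(retained.mean())


# ---------------------------------------------------------------------------
# Survival curves
# ---------------------------------------------------------------------------

def simulate_survival(d0: float, doses, seed: int | None = None, *,
                      cells_plated: int | None = None,
                      n_cultures: int = 6) -> SurvivalCurve:
    """Exponential dose-response: S(D) = exp(-D/d0).

    With ``cells_plated`` set, colony counts are drawn Binomial(cells, S) for
    ``n_cultures`` replicate cultures per dose, giving sampling noise and
    replicate SEMs; otherwise the curve is the noiseless exponential.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    doses = np.asarray(list(doses), dtype=float)
    S_true = np.exp(-doses / d0)
    if cells_plated is None:
        return SurvivalCurve(doses=doses, surviving_fraction=S_true,
                             n_cultures=1, sem=np.zeros_like(doses))
    rng = np.random.default_rng(seed)
    counts = rng.binomial(cells_plated, S_true[None, :].repeat(n_cultures, axis=0))
    frac = counts / cells_plated
    S = frac.mean(axis=0)
    sem = frac.std(axis=0, ddof=1) / math.sqrt(n_cultures)
    return SurvivalCurve(doses=doses, surviving_fraction=np.clip(S, 1e-12, None),
                         n_cultures=n_cultures, sem=sem)


# ---------------------------------------------------------------------------
# Genotyping panels
# ---------------------------------------------------------------------------

def simulate_genotype_panel(n_colonies: int, re_fraction: float,
                            amplicon_sizes: dict | None = None,
                            seed: int = 0, *, size_jitter_sd: float = 10.0) -> pd.DataFrame:
    """Synthetic diagnostic-PCR panel of Tyr+ recombinant colonies.

    Every colony shows the reconstituted TYR1 band plus the residual parental
    ty and yr1 bands; a fraction ``re_fraction`` additionally shows the
    reciprocal 'y' band.  Observed sizes get Gaussian sizing jitter
    (``size_jitter_sd`` bp) to exercise tolerance-based calling.  Returns a
    DataFrame with columns ``colony_id, band_sizes`` (semicolon-separated bp).
    """
    if not 0 <= re_fraction <= 1:
        raise ValueError("re_fraction must be in [0, 1]")
    sizes = amplicon_sizes or {"TYR1": 1360, "yr1": 1060, "ty": 700, "y": 400}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_colonies):
        alleles = ["TYR1", "yr1", "ty"]
        if rng.random() < re_fraction:
            alleles.append("y")
        obs = [sizes[a] + rng.normal(0, size_jitter_sd) for a in alleles]
        rows.append({"colony_id": f"c{i:04d}",
                     "band_sizes": ";".join(f"{s:.0f}" for s in obs)})
    return pd.DataFrame(rows)
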