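"""Classification of Tyr+ recombinants and reciprocal-exchange estimation.

Tyr+ recombinants arise in a tetraploid carrying two truncated TYR1
heteroalleles: 'ty' holds the 5' portion of the ORF (nt 1-700) and 'yr1' the
3' portion (nt 300-1358), sharing a 400 bp overlap.  A diagnostic PCR across
the locus distinguishes the four possible alleles by product size; a
crossover (reciprocal exchange, RE) within the overlap yields, besides
full-length TYR1, the overlap-only 'y' allele, so the fraction of Tyr+
colonies showing the 'y' band is a *minimal* estimate of the RE fraction.
Because sister chromatids segregate randomly at mitosis, only half of the G2
exchanges leave the 'y' allele in the selected Tyr+ daughter; assuming all
events occurred in G2 the observed fraction is therefore doubled before
multiplying by the induced Tyr+ frequency to obtain the expected RE frequency
per survivor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Allele",
    "AlleleMap",
    "GenotypeCall",
    "REEstimate",
    "overlap_length",
    "classify_genotype",
    "re_fraction",
    "expected_re_frequency",
    "estimate_re",
    "marker_retention",
]

ORF_LENGTH = 1358  # TYR1 ORF, nt (1-based inclusive coordinates)


@dataclass(frozen=True)
class Allele:
    """A TYR1-locus allele: its ORF interval and diagnostic amplicon size.

    Amplicon sizes are the printed diagnostic product sizes and are not
    recomputed from the interval (the full-length product carries 2 bp of
    primer-determined flank beyond the ORF).
    """

    name: str
    start: int  # 1-based inclusive
    end: int
    amplicon_bp: int

    def __post_init__(self):
        if not 1 <= self.start < self.end <= ORF_LENGTH:
            raise ValueError(f"{self.name}: interval must lie within (1, {ORF_LENGTH})")
        if self.amplicon_bp <= 0:
            raise ValueError("amplicon size must be positive")


@dataclass(frozen=True)
class AlleleMap:
    """The allele panel used to call genotypes from observed band sizes."""

    alleles: tuple
    tolerance_bp: int = 50

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(self.alleles))
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise ValueError("allele names must be unique")
        sizes = sorted(a.amplicon_bp for a in self.alleles)
        for s1, s2 in zip(sizes, sizes[1:]):
            if s2 - s1 <= 2 * self.tolerance_bp:
                raise ValueError(
                    f"amplicon sizes {s1} and {s2} are ambiguous at "
                    f"tolerance ±{self.tolerance_bp} bp")

    def __getitem__(self, name: str) -> Allele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)

    @classmethod
    def default(cls) -> "AlleleMap":
        """The packaged TYR1/yr1/ty/y panel (1360/1060/700/400 bp)."""
        from importlib.resources import files

        path = files("dsbrec.data").joinpath("tyr1_alleles.yaml")
        with path.open("r") as fh:
            return cls.from_yaml(fh)

    @classmethod
    def from_yaml(cls, source) -> "AlleleMap":
        import yaml

        cfg = yaml.safe_load(source)
        alleles = tuple(
            Allele(name=a["name"], start=int(a["start"]), end=int(a["end"]),
                   amplicon_bp=int(a["amplicon_bp"]))
            for a in cfg["alleles"]
        )
        return cls(alleles=alleles, tolerance_bp=int(cfg.get("tolerance_bp", 50)))


def overlap_length(interval_a: tuple, interval_b: tuple) -> int:
    """Length of the intersection of two 1-based ORF intervals, as the
    difference min(end) - max(start).

    This end-minus-start convention reproduces the conventional 400 bp for
    the ty (1-700) x yr1 (300-1358) heteroallele pair; disjoint intervals
    give 0.
    """
    (s1, e1), (s2, e2) = interval_a, interval_b
    if s1 > e1 or s2 > e2:
        raise ValueError("intervals must satisfy start <= end")
    return max(0, min(e1, e2) - max(s1, s2))


@dataclass
class GenotypeCall:
    """Allele composition called for one Tyr+ colony."""

    colony_id: str
    observed_sizes: tuple
    alleles: frozenset
    unclassified: tuple = ()

    @property
    def re_positive(self) -> bool:
        """True when the reciprocal-exchange diagnostic 'y' allele is present."""
        return "y" in self.alleles


def classify_genotype(observed_sizes, amap: AlleleMap | None = None,
                      colony_id: str = "") -> GenotypeCall:
    """Assign each observed band to the nearest expected amplicon size.

    Bands further than ``tolerance_bp`` from every expected size are reported
    as unclassified.  Ambiguity between expected sizes is excluded by
    AlleleMap validation, not re-checked per call.
    """
    amap = amap or AlleleMap.default()
    found, unknown = set(), []
    for size in observed_sizes:
        if size <= 0:
            raise ValueError("band sizes must be positive")
        best = min(amap.alleles, key=lambda a: abs(a.amplicon_bp - size))
        if abs(best.amplicon_bp - size) <= amap.tolerance_bp:
            found.add(best.name)
        else:
            unknown.append(size)
    return GenotypeCall(colony_id=colony_id, observed_sizes=tuple(observed_sizes),
                        alleles=frozenset(found), unclassified=tuple(unknown))


@dataclass
class REEstimate:
    """Minimal RE fraction among Tyr+ colonies and its phase-corrected
    expected frequency per survivor.

    The uncorrected fraction is always kept alongside the corrected
    expectation ("minimal estimate" semantics).
    """

    n_colonies: int
    n_y_positive: int
    fraction: float
    ci_low: float
    ci_high: float
    phase: str | None = None
    correction: float | None = None
    correction_source: str | None = None  # "analytic" or "simulated"
    induced_frequency: float | None = None
    expected_frequency: float | None = None
    flags: list = field(default_factory=list)


def re_fraction(calls, conf: float = 0.95) -> REEstimate:
    """Minimal reciprocal-exchange fraction: share of colonies with a 'y'
    band, with a Clopper-Pearson (exact binomial) confidence interval."""
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one genotype call")
    n = len(calls)
    k = sum(c.re_positive for c in calls)
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="beta")
    return REEstimate(n_colonies=n, n_y_positive=k, fraction=k / n,
                      ci_low=float(lo), ci_high=float(hi))


def expected_re_frequency(fraction: float, induced_freq: float,
                          phase: str = "G2",
                          correction: float | None = None) -> float:
    """Expected RE frequency per survivor.

    ``correction x fraction x induced_freq`` where the segregation correction
    is 2 for G2 events (random sister segregation hides half the 'y' alleles)
    and 1 for G1.  A Monte-Carlo correction — 1/retention_probability from
    ``karyosim.simulate_re_segregation`` — may be supplied instead of the
    analytic factor.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if induced_freq < 0:
        raise ValueError("induced frequency must be >= 0")
    if phase not in ("G1", "G2"):
        raise ValueError("phase must be 'G1' or 'G2'")
    if correction is None:
        correction = 2.0 if phase == "G2" else 1.0
    if correction < 1:
        raise ValueError("segregation correction must be >= 1")
    return correction * fraction * induced_freq


def estimate_re(calls, induced_freq: float, phase: str = "G2",
                correction: float | None = None) -> REEstimate:
    """Full RE estimate: minimal fraction (with CI) plus the phase-corrected
    expected frequency; records whether the correction was analytic or
    simulated."""
    est = re_fraction(calls)
    source = "analytic" if correction is None else "simulated"
    used = correction if correction is not None else (2.0 if phase == "G2" else 1.0)
    est.phase = phase
    est.correction = used
    est.correction_source = source
    est.induced_frequency = induced_freq
    est.expected_frequency = expected_re_frequency(
        est.fraction, induced_freq, phase, correction=used)
    return est


def marker_retention(n_tested: int, n_lost: int) -> float:
    """Percent of colonies that lost a ploidy-verification marker."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_lost <= n_tested:
        raise ValueError("need 0 <= n_lost <= n_tested")
    return 100.0 * n_lost / n_tested
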