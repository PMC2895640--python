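# Methods

## Random-breakage model and the zero-class estimator

Ionising radiation induces DSBs approximately uniformly along the genome, so
the break count of a chromosome of size *L* Mb after dose *D* krad is
Poisson with mean κ·D·L, where κ is the induction efficiency in
DSBs/Mb/krad (default 0.07, the canonical value for gamma-irradiated yeast).
A PFGE band contains only molecules with zero breaks, so

    F = I_dose / I_control = P(0 breaks) = exp(-N),   N = -ln F.

`dsb_quant.fit_dsb_density` regresses N on L. The regression is **through
the origin by default**: the Poisson model forces N = r·L exactly, and a
free intercept would let lane-loading error masquerade as breakage. A
free-intercept mode exists for diagnostics — a constant intercept is the
signature of a dose/control loading mismatch, since scaling a lane by c
shifts every N by −ln c without touching the slope. Because only intensity
ratios enter, the estimate is invariant to a global rescale of all
intensities (amount of DNA loaded).

Band handling defaults, all configurable:

* **Resolution window 250–1600 kb** (what the CHEF program separates);
  bands outside are excluded from fits. With the packaged karyotype this
  drops chromosome I (230 kb).
* **Comigration threshold 5%**: chromosomes whose sizes differ by less than
  5% of their mean (chained on the sorted size list) are merged into one
  flagged band with summed intensity, and flagged bands are excluded from
  fits by default. For the packaged karyotype this merges V+VIII, II+XIV,
  XIII+XVI and VII+XII+XV — the comigration groups seen on real CHEF gels —
  leaving six fittable single-chromosome bands.
* **F > 1 clamped to 1 and flagged** (N = 0) rather than dropped: noise can
  push a ratio past 1, and dropping such bands would bias the fit low while
  clamping preserves the band count and an audit trail.
* F ≤ 0 (signal lost) makes a band unquantifiable; it is excluded with a
  recorded reason, never converted to an infinite break count.

Repair time-courses divide the fitted density at time t by the density of
the t = 0 post-irradiation lane (pooling information across bands), giving
fraction_unrepaired(t) and its complement. The expected genome-wide burden
`expected_dsbs` is κ·D·(total genome Mb), ploidy- and replication-aware: a
G2/M tetraploid counts 8 haploid genome equivalents. With the packaged
nominal karyotype (12.068 Mb haploid) this gives 540.6 DSBs/cell at 80 krad
and 135.2 at 20 krad; the genome-size assumption is reported alongside the
value. Note the nominal chromosome XII size omits most of the rDNA repeat
expansion, a known few-percent understatement of the physical genome.

## Synthetic gel lanes (`karyosim.simulate_gel_lanes`)

Band intensity for a lane at repair time t is

    loading(lane) x copies x exp(-kappa·D·L·u(t)) x noise,

where u(t) = plateau + (1-plateau)·e^(-rate·t) is the unrepaired fraction
under first-order rejoining (rejoined molecules are assumed restored to
full length, which thins the Poisson break burden), `loading` is a per-lane
lognormal scalar (sigma = `loading_factor_sd`, default 0) and `noise` is
lognormal with mean 1 and CV = `noise_cv`. The real study does not state
its densitometry noise; the default CV of 5% is a typical stained-gel
figure and is surfaced in the config. A separate Monte-Carlo helper
(`unbroken_fraction_mc`) draws per-molecule Poisson break counts so the
closed form can be checked against simulation. What is *not* modelled: gel
physics (migration, smearing), background subtraction (inputs are net
intensities), and rDNA length heterogeneity — so passing recovery tests
demonstrates correctness of the estimators under the model's assumptions,
not robustness to gel artefacts.

## Fluctuation cultures and the method of the median

`simulate_fluctuation` grows each culture from one cell for
G = round(log2(n_final)) doublings; each generation draws
Binomial(n_wildtype, rate) new mutant daughters, and mutant lineages then
grow deterministically with the culture (no death, no fitness cost).
Because real cultures are asynchronous, each mutation is placed at a
uniform time within its generation, founding a clone of
floor(2^(G−g−1+U)) final cells. This reproduces the reciprocal clone-size
law of the continuous-time Luria–Delbrück process; a strictly synchronous
variant quantises clone sizes to powers of two and biases the
method-of-the-median estimator roughly 12% low, enough to break its own
confidence-interval calibration. The realised culture size 2^G is recorded
and used as the denominator.

`median_rate` solves r0/m − ln m = 1.24 (unique root; Brent's method) and
reports rate = m / cells_per_culture. The CI is a seeded nonparametric
percentile bootstrap over cultures (default 10⁴ resamples; root-solves are
done once per unique bootstrap median, which is only a speed optimisation).
Measured self-consistency: at generating rates 1.5–2.5×10⁻⁶, 24 cultures of
10⁷ cells, the 95% CI covers the generating rate in ≈93–95% of replicate
assays (400 assays per rate). A zero median means the rate is below the
assay's resolution: the point estimate is 0 and only an upper bound (from
the mutant-free fraction, p0 method) is reported.

## Frequencies, t tests, survival

Recombinant frequency per survivor is (selective colonies / cells plated)
divided by the complete-medium plating efficiency, each dilution-corrected;
zero selective colonies report 0 plus a one-colony resolution bound. Net
frequencies (treated − untreated) keep negative values with a flag so
averages stay unbiased; induction efficiency is the through-origin slope of
net frequency against dose.

`summary_t_test` reconstructs SDs from SEM·√n and uses the pooled-variance
test by default (df = n₁+n₂−2) because it reproduces a raw-data pooled t
exactly from that data's summaries; a Welch variant is available, and one-
vs two-tailed is caller-specified. Summary-based tests can disagree with
tests run on the underlying per-culture data when those data were paired or
unequal-variance, so p-values from summaries should be treated as
indicative unless they provably match.

Survival curves store dilution-corrected colony ratios to the dose-0
reference (S(0) = 1 by construction; sampling can push S above 1, which is
flagged, not truncated). The dose-modifying factor interpolates
log-survival linearly between measured doses and returns
dose_A(level)/dose_B(level); no parametric curve is fitted unless
requested. For exponential curves S = e^(−D/d0), halving d0 gives DMF = 2
at every level, which anchors the implementation's analytic test.

## Genotyping and the G2 segregation correction

The allele panel (TYR1 1360 bp, yr1 1060 bp, ty 700 bp, y 400 bp) ships as
a YAML fixture. Amplicon sizes are taken verbatim from the diagnostic-PCR
table rather than recomputed from ORF coordinates, because the full-length
product exceeds the 1358 nt ORF by 2 bp of primer-determined flank;
interval arithmetic is used only for `overlap_length`, whose
end-minus-max-start convention reproduces the 400 bp overlap from
(1,700)×(300,1358). Band calling assigns each observed size to the nearest
expected amplicon within ±50 bp (gel sizing error; configurable); map
validation rejects panels whose expected sizes come within twice the
tolerance of each other, so per-call ambiguity cannot arise.

The y-positive share of Tyr⁺ colonies is a **minimal** RE estimate (long
conversion tracts that erase the y allele are invisible to the assay, a
stated limitation, not modelled). `estimate_re` therefore always reports
the uncorrected fraction (with Clopper–Pearson 95% CI) alongside the
phase-corrected expectation: correction 2 for G2 (random sister segregation
hides half the y alleles from the selected Tyr⁺ daughter), 1 for G1, or
1/retention from the segregation Monte Carlo when a simulated correction is
preferred. `simulate_re_segregation` represents each homolog's sister pair
with an independent fair coin per mitosis; the G1 outcome is structurally
certain (retention exactly 1) because the exchange precedes replication.

## Pipeline, formats, determinism

All inputs are tidy single-observation-per-row tables: gel TSV
(band_id, chromosomes, size_kb, lane_id, intensity + lane metadata), colony
CSV (strain, agent, dose, dose_units, replicate, medium, cells_plated,
dilution, colonies), genotype CSV (colony_id, band_sizes as
semicolon-separated bp). Sizes are accepted in kb and held in Mb
internally. The YAML `RunConfig` round-trips losslessly, carries every
analysis switch and seed, and `run_pipeline` logs the defaults in effect;
identical config + seed gives byte-identical outputs. Validation errors
name the offending line.

## Problem sizes used in validation

Monte-Carlo checks run at 10⁴ molecule copies (breakage zero-class, 3-SE
band), 10⁵–2×10⁵ segregation trials, 400 fluctuation assays of 24 cultures
per generating rate with 2×10³ bootstrap resamples inside each, and
10³-panel binomial coverage checks — sizes at which the binomial/Poisson
standard errors are a few per mil to a few percent of the quantities being
checked, so the suite completes in seconds on one core.

## Known limitations

* Band intensities are generated from the analytic zero-class expectation
  (plus noise), not per-molecule sampling, so sub-Poisson fluctuations of
  band mass are not represented in the default tables.
* Nominal chromosome sizes understate rDNA-bearing chromosome XII.
* The fluctuation model ignores death, differential fitness, phenotypic
  lag and plating efficiency; rates inferred from real assays carry those
  caveats.
* Summary-statistics t tests cannot recover pairing or heteroscedasticity
  present in raw data.
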