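# Methods

This note documents the statistical model behind `snpresample`, the
estimators it uses, the synthetic-data generator and its calibration, the
numerical conventions, and the design choices that were genuinely open.

## 1. The resampling protocol

The object of study is a genotype matrix: diploid biallelic SNP calls
(alt-allele dosage 0/1/2, with an explicit missing sentinel) for one or
more populations. The question is the smallest per-population sample size
n at which standard diversity and differentiation statistics estimated
from n individuals stop differing materially from those estimated from the
full panel.

One *replicate* draws k loci and n individuals per population, both
uniformly without replacement, and recomputes every statistic from the
subsample alone — including allele frequencies and the per-locus typed
count N that drives the unbiased-heterozygosity correction. Replicates are
independent of one another; overlap between replicates is allowed and, for
small panels, unavoidable.

The protocol has two stages:

1. **Replicate count.** With n fixed at a deliberately small value
   (default 3, chosen so replicate-to-replicate dispersion is visible),
   the replicate count x ranges over a grid (default 10, 20, …, 100). The
   ΔK statistic (below) on the per-x summaries selects x*.
2. **Sample size.** With x = x*, n ranges over its grid (default 2, 4, 6,
   8, 10, 15) and ΔK selects n*.

Both stages run separately per parameter and per population; the
between-population stage estimates Fst on the panel of loci that survived
filtering in *every* population. Per-grid-point summaries report the mean,
SD (denominator x − 1), SE = SD/√x and the t-based confidence interval
mean ± t(level, x−1)·SE; t-based rather than normal intervals matter at
x = 10, where the critical value is 2.26 rather than 1.96.

**Fixed vs redrawn SNP panels.** By default the k-SNP panel is selected
once per analysis unit (each population, and once for the shared panel)
and held fixed across all replicates and grid points; replicates then
differ only in the individuals drawn. This mirrors a one-off random marker
selection from a pilot panel and keeps the replicate SD a pure function of
individual sampling, which is what gives the ΔK series a clean peak.
Redrawing the k loci independently for every replicate is available
(`fix_panel=False` at the protocol level, `fix_snp_panel` in the engine);
it adds a locus-sampling variance component that is constant in n and
flattens the ΔK signal.

## 2. Estimators

For a biallelic locus with alt-allele frequency p̂ = (Σ dosage)/(2N) from
N typed diploids and n_het observed heterozygotes:

- Ae = 1/(p̂² + q̂²) ∈ [1, 2]; Ho = n_het/N; He = 2p̂q̂ ≤ 0.5;
  uHe = He·2N/(2N − 1), which is unbiased for 2pq under binomial allele
  sampling.
- Loci monomorphic *in the subsample* are retained in the diversity means
  (contributing Ae = 1, He = 0): an investigator with n individuals cannot
  distinguish them from truly monomorphic loci. Loci with N = 0 in a
  subsample are undefined and excluded from that replicate's mean.
- Population-level summaries report mean ± SE over loci, with SD using the
  L − 1 denominator and SE = SD/√L.

**Differentiation.** The per-locus Nei construction with unweighted mean
frequency p̄ = (p̂₁ + p̂₂)/2 is Hs = (He₁ + He₂)/2, Ht = 2p̄q̄,
Fst = (Ht − Hs)/Ht. Algebraically Ht − Hs = (p̂₁ − p̂₂)²/2, so the plug-in
per-locus value lies in [0, 1] — but its expectation is inflated by the
sampling variance of p̂: E[(p̂₁ − p̂₂)²] exceeds (p₁ − p₂)² by
Σᵢ pᵢqᵢ/(2nᵢ). At n = 3 on a panel with mean He ≈ 0.09 that inflation is
roughly 0.15 — several times the true signal of a weakly structured pair
of populations — and it shrinks as n grows, which would make Fst look
strongly n-dependent and defeat the whole protocol.

The default estimator therefore applies the standard small-sample
correction (Nei & Chesser 1983): Hs from uHe, and
Ht = 2p̄q̄ + Hs/(2ñd) with ñ the per-locus harmonic mean of the
population sample sizes and d = 2. Under binomial sampling E[Ĥs] = Hs and
E[Ĥt] = Ht exactly, so the estimate is comparable across subsample sizes;
per-locus corrected values can be slightly negative. Overall Fst
aggregates as a ratio of sums Σ(Ht − Hs)/ΣHt over loci typed in both
populations with Ht > 0. The uncorrected plug-in form is available as
`corrected=False`; Weir & Cockerham's θ is provided as an independent
comparison estimator (it targets the Balding–Nichols θ itself, whereas
the two-population Nei Fst targets θ(d−1)/(d−θ) ≈ θ/2 — the two are not
interchangeable numbers).

## 3. The ΔK statistic

For grid values g₁ < … < g_G with replicate means m(i) and replicate SDs
s(i), interior points get ΔK(i) = |m(i−1) − 2m(i) + m(i+1)|/s(i); the
second difference is taken on successive grid points regardless of their
spacing, following the Evanno convention. The recommendation is the argmax
over defined interior points, with ties broken toward the smaller grid
value (the statistic's purpose is *minimal* sufficient sampling). Points
with s(i) = 0 are undefined and excluded rather than smoothed — zero
replicate variance means the grid point is already exact. A flatness
diagnostic (max ΔK/median ΔK) is attached to every recommendation so
"no clear peak" series are visible; values near 1 mean the peak is
noise-driven.

ΔK is invariant to adding a constant to all means and to jointly scaling
all mean-deviations and SDs; dividing by SE = SD/√x instead of SD (the
`denominator="se"` switch) rescales every value by √x at fixed x and never
moves the within-series argmax, but changes comparability across series
with different x.

Behaviour to expect: for parameters whose estimator is biased at small n
(Ae, whose plug-in homozygosity is overestimated from few individuals),
the mean curve saturates and ΔK peaks sharply and reproducibly at the
knee (n = 4 on the default panel, flatness often > 3). For parameters
that are unbiased in n (Ho, uHe, corrected Fst) the mean curve is flat,
the second difference is pure replicate noise, and the peak location is
only weakly concentrated at small n (via the larger SD at n = 2 entering
neighbouring numerators). This is a property of the statistic, not an
implementation artefact; the flatness diagnostic is the guard.

## 4. The synthetic-data generator

The generator emulates the post-QC product of a 2b-RAD-style survey of two
weakly differentiated, low-diversity populations; it is a stand-in
distributional model, not a reconstruction of any real data set.

- **Ancestral frequencies.** p₀ ~ Beta(a, b) truncated to [0.01, 0.99]
  and renormalised. The default solves b numerically (with a = 0.5) so
  that the expected within-population heterozygosity 2E[p₀q₀](1 − θ)
  equals `target_mean_he` (default 0.087, giving b ≈ 15.5): most loci
  carry a rare alternate allele, the typical shape of a low-diversity RAD
  panel. A symmetric truncated Beta cannot reach such low targets — with
  bounds at 0.01 its E[pq] is floored near 0.107 — which is why the
  asymmetric family is the default. The moment integral is evaluated by
  numeric quadrature and doubles as the oracle in the calibration tests.
- **Divergence.** Population frequencies follow the Balding–Nichols law
  pᵢ ~ Beta(p₀(1−θ)/θ, q₀(1−θ)/θ), mean p₀, variance p₀q₀θ. Matching the
  expected Nei differentiation over d populations, E[Hs] = 2p₀q₀(1−θ) and
  E[Ht] = 2p₀q₀(1−θ/d), gives Fst = θ(d−1)/(d−θ) and the closed-form
  calibration θ = d·Fst/(d−1+Fst); for d = 2 and Fst = 0.036,
  θ ≈ 0.0695. θ = 0 degenerates to pᵢ = p₀ exactly.
- **Genotypes.** Dosage ~ Binomial(2, pᵢ) per individual under HWE. A
  configurable fraction of loci is drawn instead with a heterozygote
  deficit, P(0,1,2) = (q² + Fpq, 2pq(1−F), p² + Fpq) — deficit rather
  than excess because low-diversity invasive panels typically show
  Ho < uHe. Each call is independently set missing with `missing_rate`
  (default 0.02, consistent with a panel already filtered to > 80% call
  rate).
- **Randomness.** One root seed; frequency, genotype and missingness
  draws use separate streams split per 1024-locus block, so increasing
  `n_loci` extends the panel without reshuffling existing loci, and the
  same seed reproduces the matrix bit for bit.

What the generator does *not* emulate: linkage disequilibrium between loci
(loci are exchangeable independent draws), ascertainment of SNP discovery,
genotyping error, and population-specific sample-size imbalance. Passing
tests therefore demonstrate correctness of the protocol's machinery and
calibration under an idealised exchangeable-locus model, not robustness to
those real-data features.

## 5. Locus filters

Fixed order: MAF → call rate → outlier list → HWE.

- MAF: remove iff min(p̂, 1−p̂) < 0.01, pooled over all samples
  (genotyping-level QC precedes population analysis). Loci with zero
  non-missing calls are removed under a separate `call_rate_zero` rule.
- Call rate: retain iff typed fraction is *strictly greater than* 0.80;
  a locus typed in exactly 80% of individuals is removed.
- HWE: chi-square goodness of fit with 1 df on the three genotype cells,
  no continuity correction, α = 0.05, no multiple-testing correction,
  tested within each population separately; monomorphic loci return
  (χ² = 0, p = 1). A population's own panel drops only its own failures;
  the shared panel drops loci failing in any population. On HWE-true
  data the removal fraction calibrates to α for moderate counts (the
  acceptance check uses N = 100 individuals and p ∈ [0.2, 0.8]; at
  N = 20 with a rare-allele spectrum the chi-square approximation is
  conservative and removes less than α — a property of the test itself).
- Outliers: an externally produced list of locus ids (e.g. from a
  Bayesian selection scan) is removed verbatim; unknown ids are logged
  and ignored. Outlier detection itself is out of scope.

## 6. Problem sizes and determinism

The default protocol (14,000 loci, two populations of 20, k = 3000, full
x and y grids) runs in about two seconds on one CPU; the acceptance
experiments use 20 seeded panels for the Fst calibration and 50 seeded
full protocol runs for the recommendation-distribution check, sizes chosen
to keep Monte-Carlo error well below the decision margins while the whole
suite stays interactive. All randomness flows from explicit seeds through
per-purpose split streams; identical configuration and seed reproduce
every output file byte for byte.

## 7. Known limitations

- The ΔK adaptation to diversity parameters divides by the replicate SD;
  dividing by the SE is equally defensible and is provided as a switch.
  For flat-mean parameters the recommendation is noise-driven by
  construction and should be read jointly with the flatness diagnostic.
- The corrected Fst can go slightly negative per locus and, on panels
  with truly zero differentiation, the overall estimate fluctuates around
  zero rather than being floored at it.
- The GenAlEx-dialect reader/writer implements one specific codominant
  layout (two allele columns per locus, codes 1/2, 0 missing); it is not
  a general GenAlEx parser.
- Sample sizes are equal by construction in the simulator; the estimators
  handle unequal N per locus (harmonic-mean correction), but the protocol
  draws the same n from every population.
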