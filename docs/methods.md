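# Methods

This note records the statistical models implemented in `lactqtl`, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Wood curve fitting

Each ewe-by-lactation series of daily yields is modelled as
W(t) = a t^b e^(−ct).  Because ln W = k + b ln t − c t with k = ln a, the
first-stage fit is ordinary least squares on the log scale (zero yields are
excluded and counted; fewer than three positive records on distinct days is
an error).  A nonlinear least-squares refinement on the natural scale
(parameterised in (k, b, c) so a stays positive, b bounded below by 0)
polishes the estimate; by construction it never increases the natural-scale
residual sum of squares, and a failed refinement returns the log-linear fit
flagged `non_converged`.  Fits with c ≤ 0 ("non-declining") are retained
with a flag — persistency and extended lactation are undefined for them and
propagate as missing values with a reason code, never silently dropped.

The *population* fit approximates a nonlinear mixed model with a random
ewe-by-lactation effect by a transparent two-stage procedure: per-curve
estimates of (k, b, c), then a linear fixed-effects regression of each
parameter on categorical covariates (age class, parity, birth type, milking
frequency, season — treatment-coded at stated reference levels), and
shrinkage of each raw estimate toward its fitted mean with weight
τ²/(τ² + s²ⱼ), where s²ⱼ is the per-curve OLS sampling variance and τ² a
method-of-moments between-lactation variance (floored at zero).  Factor
levels carried by a single lactation are not estimable and are pooled with
the reference level, flagged.  The deliberate trade-off: a simultaneous
marginal-likelihood fit would be statistically slightly more efficient but
is harder to test and to reason about; the two-stage fit is deterministic
and each stage has an independent oracle.

A note on the curve maximum: maxY = a (b/c)^b e^(−b) = W(t_max) with
t_max = b/c; for b = 0 the maximum sits on the boundary, (t_max, maxY) =
(0, a).

## Derived traits

* CumY(T) = a c^(−(b+1)) γ(b+1, cT), the exact integral of W on [0, T]
  (lower incomplete gamma via `scipy.special.gammainc`), cross-checked
  against adaptive quadrature in the tests.
* PersY(T) = W(T)/maxY, evaluated at T = 100 days — the reference day at
  which sheep lactation records are still dense; always in (0, 1].
* Extended lactation = [CumY(300) − CumY(100)]/CumY(100); the 300-day cut
  bounds an otherwise open-ended integral.  Both windows are configurable
  but default-locked.
* Component yields divide the composition percentage by 100
  (PY = protein% × MY/100, likewise FY, LY) so yields stay in mass units;
  the divisor cancels in every ratio trait.  SCS = log₁₀ SCC (missing for
  SCC ≤ 0), SCY = SCS × MY, UY = FY + 1.85 × PY.

## Transmitted-allele probabilities

The family is a single phase-known sire backcross, so the sire meiosis is a
two-state (Awassi/Merino) process along each chromosome.  P(A at a query
position) conditions on the *two nearest informative flanking markers* only,
under the Haldane map function r = (1 − e^(−2d/100))/2 with no crossover
interference (Kosambi is available behind a flag).  A full hidden-Markov
chain over all markers would differ only where several consecutive markers
are missing; with microsatellite spacing the flanking-marker computation is
numerically indistinguishable and exactly enumerable, which makes the
brute-force two-interval enumeration a usable test oracle.  Uninformative
or missing genotypes are skipped when choosing flanks; a daughter with no
informative marker on a chromosome gets P = ½ throughout (flagged as a
coverage gap).  Scan grids run marker-to-marker at a 1 cM default step with
all marker positions inserted.

## Mixture-likelihood scan

At each position, y_i ~ p_i N(μ_A, σ²) + (1−p_i) N(μ_M, σ²) with p_i the
daughter's transmission probability; σ is pooled across genotype classes
(the standard homoscedastic interval-mapping likelihood).  EM maximises the
likelihood (E-step: posterior allele weights; M-step: weighted means and
pooled variance), initialised from the no-QTL fit split by ±0.5 σ;
convergence at relative log-likelihood change < 1e-8 or 200 iterations,
with the monotone-likelihood guarantee making the last iterate the best.
LOD = [max log L − log L₀]/ln 10.  Peaks are classified by fixed cut-offs
(suggestive [1.75, 2.0), significant [2.0, 3.0], highly significant
> 3.0), located with leftmost tie-breaking (ties flagged), and bracketed by
the 1-LOD drop-off support interval clipped at chromosome ends.  Effects
are reported as (μ̂_A − μ̂_M)/σ₀ with σ₀ the no-QTL phenotypic SD; positive
means the Awassi allele raises the trait.  Traits are natural-log
transformed before scanning; zeros get an offset of half the smallest
positive value (applied to zeros only, recorded in the scan metadata).

At a fully informative marker the mixture MLE is algebraically identical to
two-group least squares, giving the exact identity
LOD = (n/2) log₁₀(RSS₀/RSS₁) used as a cross-method test oracle.  Under the
null at a fixed position the LR statistic is an ordinary 1-df likelihood
ratio, so E[LOD] ≈ 1/(2 ln 10) ≈ 0.217.

## Half-sib regression scan

y is regressed on x_i = 2 P_i(A) − 1;
F = (RSS₀ − RSS₁)/(RSS₁/(n − 2)) per position (monomorphic positions are
skipped and flagged).  In a single-sire family the general multi-family
half-sib regression collapses to this one within-family regression — no
across-family weighting is needed.  Chromosome-wide significance thresholds
are empirical quantiles of the permutation distribution of the scan-maximum
F (phenotypes permuted against genotype rows, 1,000 permutations by
default); experiment-wide thresholds use chromosome-wise α/26 (Bonferroni
over the autosomes), a reconstruction since genome-wide adjustments vary by
convention.  Positional confidence intervals are percentile bootstrap
intervals of the scan-peak position over daughter resamples (degenerate
resamples redrawn and counted).  QTL heritability is
1 − RMS(full)/RMS(reduced), clipped at zero.  The additive two-QTL model is
a grid search over ordered position pairs on a 2 cM sub-grid with a 5 cM
minimum separation (bounding collinearity of neighbouring transmission
scores); F(2vs0) tests both QTL against the null, F(2vs1) against the best
single-QTL fit, and the phase (coupling/repulsion) is read off the effect
signs.  All resampling takes mandatory seeds and is bit-reproducible.

## Design power

`estimate_power` reproduces the design calculation for this family size:
simulate the transmitted allele at a QTL midway between two fully
informative markers 20 cM apart, add the configured contrast (default
0.4 SD) to a unit-variance normal trait, scan the interval at 1 cM steps,
and reject when the maximum likelihood-ratio statistic exceeds the
point-wise α threshold (χ²₁ 3.84 ⇔ LOD 0.834 at α = 0.05).  With n = 172
this gives power ≈ 0.72.  Two reference points frame that number: the
full-information single-position test has the analytic ceiling
Φ(0.4·√(n/4) − 1.96) ≈ 0.746, while testing *only* the midpoint position
(information eroded by recombination on both sides, scan maximum not taken)
gives ≈ 0.65.  `scan=False` selects the single-position variant, which is
exactly size-α under the null; the interval-scan maximum carries a mild
size inflation under a point-wise threshold (≈ 0.10 across 21 correlated
positions), the usual price of scanning.

## Synthetic studies

The generator emulates the resource design: 172 daughters, 189 markers
allocated round-robin over 26 autosomes with sheep-like lengths (linearly
decreasing 250 → 40 cM, ≈ 3,800 cM genome; true per-chromosome spacings are
study-specific and configurable), transmitted haplotypes simulated as the
same Haldane two-state process the analysis assumes, 90% of markers
informative and 5% of calls missing by default.  Milk yield is recorded
every second day and composition weekly; lactation length is
100 + Exponential(90) days capped at 300, which mirrors the sharp attrition
of records after day 100 (about half the lactations reach day 150, a third
day 200).  Wood parameters are drawn per ewe-by-lactation from
(k, b, c) ~ N((0.35, 0.35, 0.025), (0.35, 0.10, 0.005)²) (b, c truncated
positive) with multiplicative lognormal measurement noise (σ = 0.15 on the
log scale); these values put milk persistency near 0.25 ± 0.12 and peak
yield near 1.5 L/day, i.e. inside the descriptive ranges of the study
population the package targets.

QTL act in one of two modes.  *Parameter* mode shifts k, b or c by an
amount solved (at the population-mean curve) so the derived measure moves
by the calibrated trait shift — biologically natural, e.g. a QTL on c
changes persistency.  *Direct* mode (the default for calibration work)
moves the derived trait itself: the per-ewe decline rate is re-solved so
her derived measure shifts exactly by δ = e·σ₀/√(1 − e²/4), which makes the
realised genotype contrast equal e phenotypic SD once the QTL variance is
included.  True transmitted states at every QTL are returned separately so
recovery tests never depend on re-inferring them.

What the generator does **not** emulate: population-level linkage
disequilibrium, maternal genotypes and dam-side inheritance (absorbed into
residual noise, consistent with the half-sib analysis model), genotyping
error beyond missingness, multi-generation pedigrees, and
season-by-lactation environmental trajectories.  Passing tests therefore
demonstrate the estimators' behaviour under the assumed segregation and
curve models, not robustness to violations of them.

## Numerical details and edge cases

* Log-scale OLS covariance feeds the shrinkage weights; curves with only
  3 points get no covariance and inherit the largest observed sampling
  variance (maximal shrinkage).
* EM positions that fail to converge within 200 iterations are flagged,
  and the (monotone) last iterate is used.
* LOD is floored at 0; scan-peak ties break leftmost and are flagged.
* `cumulative_yield` raises for non-declining fits (the integral diverges
  as T grows and the trait is reported missing upstream).
* The pipeline excludes ewes without genotypes from scans but keeps them in
  descriptive tables, so per-trait n varies.
* Pipeline scans default to a 2 cM step (1 cM for single-chromosome CLI
  scans); acceptance-scale simulations use 2 cM steps and chromosome sizes
  chosen to keep the full suite around half a minute.

## Known limitations

* The two-stage population fit understates uncertainty relative to a joint
  mixed model when curves are very short (few records per lactation).
* Flanking-marker conditioning ignores information from beyond the nearest
  informative markers; with long runs of missing genotypes the mixture
  probabilities are mildly conservative.
* The experiment-wide Bonferroni adjustment over 26 autosomes is
  conservative relative to a genome-wide permutation.
* Direct-mode QTL calibration is exact for the configured measure but the
  induced shift on *other* derived traits of the same curve is whatever the
  shared parameters imply.
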