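# Methods

This note documents the statistical models implemented in `cellmr`,
the defaults and their rationale, what the simulator does and does not
emulate, and the numerical choices made where the design was open.

## Fine-mapping (`cellmr.finemap`)

Regional association z-scores are modelled as `z ~ N(R b, R)` where `R`
is the LD (genotype correlation) matrix and `b` a sparse vector of
standardized causal effects written as a sum of `L` single effects.
Each single effect picks one SNP (uniform prior over the region) and an
effect size `N(0, σ₀²)`. Fitting is by iterative Bayesian stepwise
selection: each effect is refit against the residualized z-scores,
where — because the sufficient statistics are standardized — the
per-SNP single-effect Bayes factor has the closed form
`log BF = ½ log(1/(1+V)) + ½ z_r² V/(1+V)` with `V = σ₀²` and `z_r` the
residual z. The per-effect prior variance is estimated each sweep by
bounded one-dimensional maximization of the single-effect marginal
likelihood on the log scale and floored at zero: an effect whose
optimal marginal likelihood does not beat the point null collapses to a
uniform inclusion vector and never emits a credible set, which prevents
phantom sets under the null.

The variational objective is tracked per sweep. The KL term of each
effect is computed directly against its prior (categorical part plus
normal-vs-normal part), not via residual identities, so the trace is
monotone to numerical precision; convergence is declared when it moves
less than `tol`.

Credible sets take, per non-null effect, the smallest
inclusion-probability-ordered prefix reaching the coverage target
(default 0.9); sets with minimum absolute pairwise LD (purity) below
0.5 are discarded and duplicates removed. Defaults `L = 10`,
`max_iter = 100`, `tol = 1e-3`, ridge `1e-6` on near-PSD LD matrices
mirror the published defaults of the sum-of-single-effects literature.
A strongly non-PSD LD matrix (minimum eigenvalue below −0.05) is
rejected rather than silently repaired, since it indicates a mismatched
reference panel.

Known degenerate case: two causal SNPs in unlinked blocks with *exactly*
equal |z| form a symmetric fixed point of the coordinate ascent (each
effect splits its mass between the two blocks). Continuous data never
hits it; the test suite perturbs planted strengths accordingly.

## Colocalization (`cellmr.coloc`)

Per-SNP evidence is the Wakefield asymptotic Bayes factor
`log ABF = ½ log(1−r) + r z²/2`, `r = W/(V+W)`, with prior effect SD
0.15 for quantitative and 0.2 for binary traits, and per-SNP prior
probabilities `p1 = p2 = 1e-4`, `p12 = 1e-5` — the documented defaults
of the standard colocalization model, adopted because the procedure
this package implements specifies "default parameters". The five
hypothesis masses are

    H0: 1          H1: p1·ΣBF1       H2: p2·ΣBF2
    H3: p1·p2·(ΣBF1·ΣBF2 − Σ BF1ᵢBF2ᵢ)     H4: p12·Σ BF1ᵢBF2ᵢ

accumulated entirely in log space (log-sum-exp), so posteriors stay
finite and normalized for |z| at least up to 40. The GWAS is always
trait 1 and the eQTL trait 2, fixing the meaning of PPH1/PPH2 in
reports. In a single-SNP region the H3 mass is exactly zero.

When both traits' fine-mapping yields credible sets, every set pair is
enumerated separately using the per-SNP log Bayes factors of the
corresponding single effects (the multiple-causal-variant mode); with
one effect per side this reduces, verified to 1e-8, to the plain
enumeration on those Bayes factors. Without credible sets on either
side the region falls back to marginal-BF enumeration, and the fallback
is recorded. Colocalization is declared at PPH4 strictly above 0.8.
The reported causal variant maximizes the per-SNP H4 posterior, with
ties broken by smaller GWAS p-value then lexicographic id; when several
set pairs colocalize for one gene, all pairs are reported and each
contributes its top SNP.

## Instrument pipeline (`cellmr.instruments`)

Stage order is fixed: relevance filter (exposure *P* < 5 × 10⁻⁸, pooled
union of top causal SNPs across a cell type's colocalized genes) →
confounder filter → LD clumping → proxy substitution → harmonization →
radial outlier removal → F-statistic. Each stage logs in/out counts and
drop reasons.

* **Confounder filter.** A local table of variant-confounder
  associations (e.g. a PhenoScanner export: snp, confounder, p) replaces
  any network lookup. A candidate is dropped if it, or any proxy at
  r² > 0.8 within the loaded LD matrix, associates with a confounder at
  p below a configurable threshold (default 5 × 10⁻⁸, since no
  confounder-specific threshold is prescribed by convention).
* **Clumping.** Greedy by ascending p (ties by position, then id, making
  the result order-independent): keep a SNP unless an already-kept SNP
  on the same chromosome lies within 10,000 kb with r² > 0.001. Pairs
  absent from the LD matrix count as unlinked.
* **Proxy substitution.** Index SNPs missing from the outcome are
  replaced by their highest-r² proxy (r² > 0.8) present in both
  datasets; provenance records the original SNP and r².
* **Harmonization.** Outcome records are aligned to the exposure's
  effect allele: swapped alleles negate the outcome beta and flip its
  frequency; non-palindromic allele pairs reported on the opposite
  strand are complemented first. Palindromic (A/T, C/G) variants are
  ambiguous: they are dropped when the minor-allele frequency exceeds
  0.42 in either dataset (i.e. EAF in (0.42, 0.58)) or when a frequency
  is missing, and otherwise oriented by whether the two frequencies
  fall on the same side of 0.5. Harmonization is involutive.
* **Radial outlier removal.** Per-SNP ratio estimates with first-order
  radial weights `w = β_exp²/se_out²` are fit by origin-constrained
  (IVW) and intercept (Egger) weighted regression on the radial scale;
  each SNP's heterogeneity contribution `Q_j = w_j(ratio_j − fit)²` is
  referred to χ²(1) and the union of SNPs flagged at α = 0.05 by either
  fit is removed in a single pass (an `iterate` option repeats to
  exhaustion). With first-order weights the iteratively-reweighted loop
  converges immediately; the tolerance parameter exists for interface
  parity. Below three instruments the filter passes through.
* **Strength.** `R²ᵢ = βᵢ²/(βᵢ² + SEᵢ²N)` summed over instruments,
  `F = R²(N−k−1)/(k(1−R²))`; F < 10 flags a weak set.

## MR estimators and diagnostics (`cellmr.mr`)

All ratio variances use first-order delta approximations; second-order
weights are not implemented, matching common practice. Normal-theory
95% CIs for Wald/IVW/Egger/RAPS; percentile bootstrap CIs (seeded
parametric bootstrap over the summary statistics, default 1000 draws)
for weighted median and mode.

* **IVW**: origin-constrained WLS of outcome on exposure betas with
  weights `1/se_out²`; multiplicative random effects inflate the fixed
  SE by `max(1, √(Q/(k−1)))`.
* **MR-Egger**: WLS with intercept after orienting all exposure effects
  positive; the intercept estimates directional pleiotropy, Rucker's Q′
  scales the SEs as above.
* **Weighted median**: inverse-variance-weighted 50th percentile of the
  ratio estimates with midpoint-cumulative linear interpolation.
* **Weighted mode**: Gaussian-kernel weighted density of the ratios,
  bandwidth `0.9 · (weighted MAD scale) · k^(−1/5)` times a
  configurable factor (default 1); density grid of 2048 points spanning
  the ratio range ± 3 bandwidths; exact density ties resolve toward the
  smaller ratio by grid order.
* **RAPS**: profile-score estimating equations with Huber ψ (tuning
  constant 1.345) on standardized residuals
  `t_j = (Γ_j − βγ_j)/√(se_Γ² + β²se_γ² + τ²)`; β by bracketed root of
  the robust score, overdispersion τ² ≥ 0 by the companion moment
  equation centered at `E[ψ(Z)Z] = 2Φ(1.345) − 1`; sandwich SE from the
  numerical derivative of the score (bread) and the empirical score
  variance (meat).
* **PRESSO global test**: observed weighted residual sum of squares
  around leave-one-out IVW expectations; the null distribution is
  simulated parametrically (default 1000 draws) and the Monte-Carlo p
  carries the +1 correction so it is never exactly zero.
* **Decision tree**: single instrument → Wald; Cochran Q, Egger
  intercept and PRESSO all p > 0.05 → IVW; pleiotropy detected with
  Q′ p > 0.05 → Egger; otherwise → weighted median (preferred over
  weighted mode for power; both are always reported). A diagnostic that
  cannot be computed (e.g. PRESSO below four instruments) counts as
  non-significant but marks the choice "diagnostic-incomplete" rather
  than hiding the gap.

## Orchestration (`cellmr.orchestrate`)

The multiple-testing family is outcomes × cell-type contexts per
exposure (e.g. 18 × 10 = 180, threshold 0.05/180 ≈ 2.78 × 10⁻⁴);
different exposures are corrected independently. Per-task RNG seeds
derive from the run seed through a seed sequence, so runs are
deterministic and byte-identical under a fixed seed. Contexts with no
eQTL records are skipped with a log entry; contexts whose QC leaves no
instruments emit a `no-instruments` row rather than aborting. Pooled
candidate instruments from different gene regions are given a
block-diagonal combined LD matrix (cross-region LD treated as zero).

## Simulator (`cellmr.simulate`)

Regional summary statistics are drawn directly at the z-score level,
`z ~ N(R z_true, R)` — exactly the model the fine-mapping and
colocalization math assumes — with betas and SEs back-computed on the
standardized-trait scale (`se = 1/√(2·maf·(1−maf)·n)`). LD is
block-diagonal AR(1) (default block size 20, ρ = 0.9); MAFs are uniform
on [0.05, 0.5]; a configurable fraction of variants gets palindromic
alleles so harmonization paths are exercised. Default effective sample
sizes (GWAS 100,000; eQTL 200) echo the scale disparity between
biobank GWAS and single-cell eQTL studies. Genotype panels, when
requested for VCF-based LD estimation, are drawn as binary Markov-chain
haplotypes whose correlation decays exactly geometrically, matching the
AR target; with strongly heterogeneous allele frequencies the clipped
conditional probabilities slightly attenuate realized LD.

The MR generator draws exposure effects with a minimum magnitude
(default 0.05, keeping instruments strong) and random reported-allele
signs, and forms outcome effects `Γ = β·γ + pleiotropy + noise`.
Directional pleiotropy is planted in the exposure-increasing allele
orientation — the direct effect flips with the reported allele exactly
as the betas do — since that is the frame in which "directional" is
defined and in which Egger regression operates. The end-to-end
generator places each gene in its own far-apart region, shares the
GWAS causal variant with the eQTL only in effect-carrying contexts,
and routes the outcome effect through the *true* marginal exposure
effects so exposure and outcome noise stay independent.

What the simulator does **not** emulate: real human LD maps and
allele-frequency spectra, sample overlap between exposure and outcome
studies, winner's-curse selection of the GWAS itself, uncertainty in
the LD reference, or cell-type expression abundances. Passing
calibration tests therefore demonstrates internal statistical
correctness under the assumed summary-statistic model, not robustness
to those real-data complications. A small winner's-curse attenuation
of end-to-end estimates (top colocalized variants are selected partly
on upward exposure noise) is visible in simulation and is inherent to
the procedure, not a defect of the generator.

## Problem sizes used in validation

Calibration suites use 200 simulated regions (60–100 SNPs each) for
colocalization and fine-mapping coverage, 500 replicates for estimator
recovery, 200 for diagnostic null calibration, and 100 end-to-end
pipeline runs with 15 genes per context — sizes at which the binomial
Monte-Carlo error of the checked rates is comfortably below the margins
asserted.

## Known limitations

No liftover between genome builds; no Steiger directionality filtering;
no multivariable MR or PRESSO outlier-correction step (radial filtering
handles outliers upstream); no masking-based conditional
colocalization; no individual-level-data fine-mapping. The confounder
filter consumes a local table only and searches proxies within the
loaded LD matrix.
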