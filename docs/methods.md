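# Methods

This note documents the statistical conventions, the synthetic-data model
and the numerical choices the package makes where the field's practice is
genuinely open.

## Data model and aggregation

The single input currency is a long table of strictly positive
concentrations (µg g⁻¹ dry weight) keyed by (site, medium, replicate,
element).  Element symbols are canonicalized case-insensitively ("AL" → "Al")
to prevent silent key mismatches.  Values at or below a detection limit are
not imputed; the table simply refuses non-positive entries.  Replicates are
collapsed to the arithmetic site mean **on the raw scale** before any
site-level statistic (descriptive tables are conventionally reported on raw
concentrations); aggregation is idempotent and never changes the set of
(site, medium, element) keys.

## Index conventions

* **EF** uses site-matched soil and a configurable reference element
  (default Al, the usual crust-conservative normalizer).  The reference
  element is excluded from EF output — its EF is identically 1.
* **CF** categories use left-closed/right-open bins
  [0,1) [1,2) [2,3.5) [3.5,8) [8,27) [27,∞).  Published statements of this
  scale overlap at the boundaries ("2 to 3.5", "3.5 and 8"); a deterministic
  convention is required, and left-closed is the one consistent with
  "CF < 1" being strictly the lowest category.  CF = 1.0 therefore falls in
  C2: the background site itself classifies as "suspected", which is a
  boundary artifact worth knowing about when reading reports.
* **Per-element CF summaries** report *both* the mean over sites and the max
  over sites, with the category tied to the mean.  Survey reports commonly
  conflate the two (a "mean CF" row that actually holds column maxima while
  the category row tracks the means); emitting both removes the ambiguity.
* **Accumulation ratios** are the mean ± sample SD of per-site ratios
  (mean-of-ratios).  The ratio of across-site means is a different, smaller
  statistic under between-site heterogeneity and cannot reproduce published
  ratio tables computed per site.

## Inference conventions

* Concentrations are transformed with log10 before parametric analysis
  (configurable: `log10`, `ln`, `identity`).  Trace-metal data are positive
  and right-skewed; the log transform removes most of the skewness.
* The post-hoc procedure behind the compact letter display is Tukey HSD at
  α = 0.05.  Published tables print letters without naming a pairwise
  procedure; Tukey is the standard choice after a one-way ANOVA.  The letter
  display uses the insert-and-absorb algorithm, letters assigned in
  descending order of group mean; when all groups are identical (zero
  within- and between-group variance) every group receives "a".
* Pearson p-values are two-sided from t = r·√((n−2)/(1−r²)) on n−2 degrees
  of freedom.  Rendered tables print r, p and CF to 3 decimals (so very
  small p appears as "0.000") and concentrations to 3 significant figures;
  machine output keeps full precision.
* Factoring is the principal-component method on the correlation matrix:
  loadings are eigenvector × √eigenvalue, retention is strictly
  eigenvalue > 1 (Kaiser; ties at exactly 1 are not retained, and the
  degenerate identity-correlation case warns "no factor retained").
  Column signs are fixed so the largest-magnitude loading is positive,
  which makes output deterministic across linear-algebra backends.  The
  solution is unrotated by default — the bipolar loading pattern typical of
  published two-factor metal tables is characteristic of unrotated
  components — with varimax available behind a switch.  Variance percentages
  are 100·eigenvalue/p for every component and always sum to 100; the full
  (unretained) loading matrix reconstructs the correlation matrix exactly.
* The pipeline's correlation and factoring stages exclude the reference
  element: it is the normalizer, not an analyte, and by construction it
  carries no source signal.

## The synthetic survey generator

The generator exists so that every analysis stage has a no-download
parameter-recovery test.  On the log10 scale, for site *s*, medium *m*,
replicate *t*, element *e*:

    soil:   log10 C = log10 μ(soil, e) + u(e, s) + ε_rep
    plant:  log10 C = log10 μ(m, e) + Σ_k λ(e, k) f(k, s) + β(e) u(e, s)
                       + ε_site + ε_rep

with soil site deviation u(e, s) = γ(e) f(k(e), s) + δ(e, s).

Design choices and defaults (profile `src/mossmetal/profiles/default.yaml`,
version 1):

* **Layout** — 9 sites × {moss, two leaf species, soil} × 3 replicates ×
  12 metals + Al, matching the survey design the analysis targets.  Site
  codes follow the emulated survey (HZ background campus, TR/GS roadside,
  WS/WB industrial).
* **Baselines** — the published per-medium mean concentrations; the moss
  baseline is the leaf_a baseline times the published per-element moss/leaf
  accumulation ratio (range 4.08–51.3), so the noise-free moss/leaf_a ratio
  equals the multiplier exactly.  Al baselines (moss 3000, leaves 150, soil
  70000 µg/g) are typical crustal/plant values; Al carries no source
  loading, no coupling and no enrichment.
* **Sources** — two factors with disjoint element sets: "traffic" loads the
  Cu, Pb, As, Ag, Mo analogues at λ = 0.45 and Cd, Zn weakly at 0.35;
  "industry" loads V, Cr, Ni at 0.45.  The weak Cd/Zn loadings mirror the
  moderate first-factor loadings such surveys report and, just as
  importantly, avoid pure-noise elements whose sample eigenvalues at n = 9
  straddle 1 and make strict Kaiser retention unstable.
* **Site scores are fixed design parameters**, not random draws: they encode
  land-use-driven source strength (traffic scores peak at the roadside
  sites, industry scores at the industrial sites, background exactly 0) and
  are scaled so the two score vectors are nearly orthogonal across the nine
  sites.  Random scores at n = 9 leave the factors substantially correlated
  in-sample and recovery unreliable.
* **Soil coupling** — the Mn and Co analogues take their source exposure
  *through* the soil: their soil deviation contains γ·f (the source
  contaminates surface soil) and the plants inherit the whole soil deviation
  with β = 1.  This reproduces the empirical signature of soil-coupled
  elements — high soil–plant r together with membership in the source factor
  — which is unattainable if coupling is modelled as an independent soil
  noise term (then r² plus factor communality cannot exceed 1, and any
  parameterization trades factor recovery against coupling strength).
  Setting β = 0 severs the plants from soil entirely, which is the null
  case used to calibrate the coupling test.
* **Noise** — lognormal throughout (additive on log10): σ_site = 0.05,
  σ_replicate = 0.02, σ_soil = 0.12.  These are deliberately low-noise
  values: the default profile is built for reliable structure recovery at
  nine sites, and its source contrasts are therefore stronger than a
  typical mildly polluted city (synthetic CF values reach the C4–C5 range
  at the roadside sites, versus C3–C4 maxima in the emulated survey).

What the generator does **not** emulate: spatial autocorrelation between
sites, temporal dynamics, censoring at detection limits, inter-element
measurement-error correlation, and analytical recovery biases.  Passing
recovery tests therefore show that the estimators find the planted
structure under the stated model, not that nine real sites suffice to
separate real sources.

## Recovery and calibration checks

* Factor recovery is asserted on varimax-rotated loadings: the planted
  pattern is disjoint simple structure, and rotating the retained components
  toward simple structure is precisely what the rotation switch is for;
  unrotated components of two-block data are general/contrast mixtures.
  Congruence (Tucker's coefficient) between estimated and planted columns
  must exceed 0.9 after the best column matching.
* Moss/leaf multiplier recovery is asserted on the log10 scale (mean of
  log10 per-site ratios against log10 a_e, 3 Monte-Carlo SEs over 30
  replicate surveys).  On the log scale the generator's noise is additive
  and the estimator exactly unbiased; the arithmetic mean-of-ratios carries
  a lognormal bias factor exp((ln10·σ_Δ)²/2) that would miscalibrate a
  3-SE comparison as replication grows.
* The coupling test's type-I error is checked under the zeroed-sources null
  (all λ and β zero, so all twelve elements give independent plant/soil
  draws) over ≥ 2000 element-level replicates against the binomial 99 %
  band around 0.05.
* Problem sizes used by the test suite: the pinned low-noise fixture is one
  1404-record survey; recovery uses 30 surveys; calibration ~160 surveys.
  The whole suite runs in well under a minute.

## Known limitations

* With nine sites, ranking elements by correlation is intrinsically noisy
  (the null sampling SD of r is ≈ 0.35); recovery tests pin seeds and the
  defaults were chosen so the checks hold across seeds with wide margin,
  but single real surveys of this size should treat correlation rankings
  with caution.
* Kaiser retention on a 12-variable correlation matrix estimated from nine
  sites is jumpy under weak structure; the degenerate and no-factor paths
  are handled, but no parallel-analysis alternative is implemented.
* The CF of the background site's own medium is 1 by construction; an
  element whose published background differs from the configured background
  site cannot be reproduced and is flagged rather than guessed (see
  `reference.CF_NONREPRODUCIBLE`).
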