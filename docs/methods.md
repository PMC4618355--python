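# Methods

## The flux-fitness landscape

Growth rate is modeled as a saturating function of the functional dosage of
an essential enzyme, `f(d) = a·d/(b+d)` with `d = A·(kcat/KM)`, where `A` is
the intracellular abundance relative to wild type and `kcat/KM` the catalytic
efficiency (μM⁻¹s⁻¹). The model assumes (i) the enzyme's pathway flux limits
growth, (ii) flux is first-order in functional enzyme at low dosage and
saturates at high dosage, and (iii) all other determinants of growth are
shared across strains. Under these assumptions `a` is the plateau growth rate
(h⁻¹) and `b` the dosage at half-maximal growth; both absorb the topology of
the surrounding metabolic network and are treated as free parameters.

Fitting is nonlinear least squares on `(a, b)` in log space (positivity
enforced by parameterization), initialized at `a₀ = max` observed growth and
`b₀ = median` dosage, with relative tolerances of 1e-15 (`scipy.optimize.
least_squares`). Strains with missing dosage (abundance "n.d.") are dropped
and reported; an explicit exclusion list removes designated outliers from the
fit (two named presets ship: the severe-fitness set of six strains, and the
five-strain subset used for fitting, which omits the one strain whose enzyme
could not be purified). Significance is an F-test of the two-parameter fit
against the constant-mean model; the residual report flags strains more than
a configurable threshold (default 0.1 h⁻¹, about a sixth of the default
plateau) *below* the fitted curve as barrier candidates.

Degenerate inputs: fewer than three usable strains is an error, as is an
all-equal dosage vector (a and b are then jointly unidentifiable).

## Cross-property statistics

The correlation landscape is Spearman's rho with average ranks for ties,
computed per property pair with pairwise deletion of missing values and a
minimum of 5 complete pairs per cell. For n ≤ 9 the two-sided p-value is
exact, computed by full enumeration of rank permutations (scipy provides
only the t-approximation); beyond that the t-approximation is used. No
multiple-testing correction is applied by default (raw p-values are what the
screen reports); Benjamini–Hochberg can be layered on by the caller.

The net-charge regression fits growth on the shifted squared charge
`(q + c)²` by OLS with `c` fixed (default 3.5, i.e. an optimum at q = −3.5)
or estimated by a bounded 1-D search over `c` minimizing the residual sum of
squares. Distribution shifts between the naive and evolved phase use the
two-sample Kolmogorov–Smirnov test (scipy's exact method for small samples),
with the direction taken from the sign of the mean difference.

## Sequence and biophysical descriptors

*Codon signature.* Codon "score" is the frequency of a codon **within its
synonymous family** of the standard genetic code — the only reading that
makes "highest-scoring codon" a per-amino-acid choice. Back-translation maps
each residue to its family-maximal codon; ties break alphabetically, so the
operation is deterministic. A 6×His tag is construct engineering, not a
property, and is not appended by any descriptor.

*CAI.* Sharp & Li: relative adaptiveness `w = family_freq / max family_freq`
per family; CAI is the geometric mean of `w` over informative codons, with
single-codon families (ATG, TGG) and stops excluded and zero-frequency
codons floored at `w = 0.01` before the log.

*Net charge.* Henderson–Hasselbalch sums over ionizable side chains (D, E,
C, Y acidic; K, R, H basic) with an EMBOSS-style pKa table shipped in
`seqprops.DEFAULT_PKA` (D 3.9, E 4.1, C 8.5, Y 10.1, K 10.8, R 12.5, H 6.5;
termini 8.6/3.6). Termini are excluded by default so side-chain-only charges
are reproducible; any pKa set can be passed in.

*Percent identity.* Needleman–Wunsch global alignment (BLOSUM62, gap open
11 / extend 1, via Biopython's `PairwiseAligner`); identity = matches /
alignment columns, counting internal but not terminal gap columns, so
identical sequences score exactly 100.

*mRNA window.* Coordinates are 0-based half-open throughout. The folding
window is 42 nt starting at a signed offset from the A of the start codon;
both the near-start offset (−4, the default) and the far-upstream one (−50)
are supported, since both conventions appear in practice. The folding free
energy itself is left to external RNA-folding tools.

*Apparent Tm.* The thermogram peak after subtracting the straight line
through the first and last grid points, optionally smoothed by a centered
odd-width moving average; by construction the estimate is invariant to any
affine-in-temperature baseline. A flat post-subtraction signal raises a
no-transition error rather than returning a spurious peak.

## Enzyme kinetics and growth curves

Progress curves follow `dS/dt = −kcat·E0·S/(KM+S)`; the closed form is
`S(t) = KM·ω(ln(S0/KM) + (S0 − kcat·E0·t)/KM)` with ω the Wright omega
function (ω(x) = W(eˣ)), which avoids the overflow the naive Lambert-W form
hits when S0 ≫ KM. Fitting is joint least squares across curves on substrate
concentration in log-parameter space; absorbance inputs convert via a fixed,
configurable extinction coefficient. When every curve starts far below the
fitted KM only the ratio kcat/KM is constrained, and the fit carries an
identifiability flag.

Growth curves are fit with the modified Gompertz model on log OD,
`ln(OD/OD₀) = c + A·exp(−exp(μe/A·(λ − t) + 1))`, whose μ is the maximal
specific growth rate (h⁻¹) and λ the lag; the free intercept `c` makes the
fit exact when the generating trajectory does not pass through the first
observation. Because the model acts on log OD, the rate is invariant to
rescaling OD by a positive constant. A fallback log-linear regression over
the longest window with near-linear log-OD handles non-Gompertz shapes, and
a series with under ~5% net OD increase returns rate 0 with a no-growth
flag. The Gompertz choice is this package's; published growth assays cite a
variety of parametric models.

Serial-passaging doublings are `passages × log₂(dilution factor)` — a pure
bookkeeping utility (note that 31 passages at a 1:100 dilution give ≈206
doublings; claims of larger generation counts require assumptions beyond
this formula).

## Proteome z-scores and group shifts

Relative abundances (strain/wild-type) are logged base 10 into LRPA `Y`;
zeros and genes undetected in the reference become missing. Each strain
column is standardized with the sample standard deviation (n−1):
`z = (Y − ⟨Y⟩)/σ_Y`, so per strain the z-scores have mean 0, sd 1, and sum 0
over quantified genes, and the operation is idempotent. Inter-proteome
similarity is Pearson correlation on z-scores over the shared quantified
genes (Spearman selectable). The group screen applies a two-sample KS test
per gene group between the pre and post z-value sets (exact p when the
smaller set has ≤ 25 genes, asymptotic above), takes the direction from the
group-mean difference, filters at raw p < α (default 0.01) with groups under
5 genes skipped, and applies no cross-group multiplicity correction by
default. Group membership may overlap.

A caveat the test suite documents explicitly: the two-sample KS statistic is
discrete, so its null p-values are conservative (stochastically larger than
uniform). Calibration checks therefore assert the absence of
anti-conservatism and rejection rates at or below nominal α, not literal
uniformity.

## The synthetic-data generator

The generators emulate the measurement structure the analysis assumes, under
the study's default design: **35 strains, 6 of them barrier strains**, Tm ~
Uniform(42, 63) °C (the mesophilic range), log10 catalytic efficiency
uniform over two decades centered on the wild-type value, and growth
generated from the landscape with `a = 0.6 h⁻¹`, `b = 1.0` plus additive
Gaussian noise (default sd 0.02 h⁻¹, ≈5% of typical growth). Abundance
increases with Tm (lognormal noise, sd 0.4 on the log scale), reflecting
faster proteostatic turnover of less stable folds; promoter activity is
inversely related to functional dosage (the starvation feedback); barrier
strains carry net charges further from the −3.5 optimum than the rest.

Barrier strains are drawn from the top 40% of intrinsic dosage — the
characteristic phenotype is a highly active enzyme whose strain barely
grows, i.e. a clear off-curve outlier. Their *functional* naive dosage is
suppressed 100-fold (hence near-zero growth); their *measured* total-lysate
abundance is treated separately, because total lysate also counts
nonfunctional protein: about a third of barrier strains collapse below the
detection limit (reported "n.d."), the rest are measured at half their
intrinsic abundance. After the simulated evolution phase the suppression is
lifted and abundances rise modestly (~1.25×) across the board.

Proteome pairs are generated directly on the z scale (background N(0, 1),
10^Y written as relative abundance): strains within a condition share a
per-gene latent component giving expected pairwise correlation ρ (default
0.4), and planted groups receive a fixed z-shift in the post matrix.

What the generator does **not** emulate: measurement error on Tm and
kcat/KM, batch effects and normalization artifacts of TMT quantification,
missingness mechanisms other than a hard detection limit, phylogenetic
correlation among orthologs, and any coupling between sequence descriptors
(GC, CAI, identity) and phenotype. Tests passing on synthetic data therefore
validate the estimators and their statistical calibration — not the claim
that real measurements satisfy the generating assumptions.

## Problem sizes and tolerances

Statistical guarantees in the test suite and acceptance script use: exact
landscape recovery at 35 strains without noise (rel. 1e-6); 200 seeds at 5%
noise for median-relative-error bounds; 100 seeds for the barrier-scenario
correlation transition and the planted-shift detection rate (50-gene group,
+1.5z, 2000-gene background); 1000 null groups of 50 for type-I calibration;
progress-curve closed form vs a stiff LSODA integration to < 1e-6 μM. These
sizes keep the full suite at well under a minute of compute while leaving
the Monte-Carlo bounds comfortably away from their thresholds.
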