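# Methods

This note documents the models, numerical conventions and design choices
behind `rilqtl`, and what the synthetic-data tests do and do not
demonstrate about real panels.

## Data model

The coordinate system is a table of nonoverlapping genomic windows per
chromosome arm (0-based half-open bp coordinates, BED-like on disk), each
nominally containing 1,000 ancestral-population SNPs (~19 kb). A window's
genetic position is its cM midpoint; all genetic distances (peak
separation, linkage) use these midpoints. Genotypes are ancestry dosages:
0 = ancestral-population homozygote, 1 = heterozygote, 2 =
derived-population homozygote, NA = missing. Downstream scans are
complete-case per window: a RIL missing at the tested window is dropped
for that window only.

## Synthetic panels

The generator emulates two real biparental RIL panels (an Ethiopia- and a
France-derived cross against Zambia): 278 or 328 lines, mean derived
ancestry 67.84% / 77.88%, residual window heterozygosity 8.71% / 5.3%,
five arms (X, 2L, 2R, 3L, 3R) with approximate fly map lengths, scaled to
~1,030 windows.

Ancestry along each arm is a Markov tract process on the genetic axis,
not an explicit multi-generation pedigree: breakpoints fall as a Poisson
process at `effective_meioses` per Morgan and each tract draws derived
ancestry independently. The analyses downstream depend only on marginal
ancestry proportions, heterozygosity, and tract-scale linkage, so this
calibrated reduced model is sufficient, with one knob
(`effective_meioses`, default 15/Morgan, mean tract ≈ 6.7 cM ≈ tens of
windows) controlling tract length. The true intercross population size
behind the real panels is not published, so tract-length calibration is
approximate by design.

Residual heterozygosity is overlaid as a second two-state tract process
(stationary heterozygous fraction = target; heterozygous tracts at half
the homozygous tract scale), mimicking the contiguous heterozygous runs
left by incomplete inbreeding rather than i.i.d. per-window flips.
Because heterozygous windows contribute dosage 1, the tract-level derived
probability is adjusted analytically, p' = (p − h/2)/(1 − h), so the
realized panel mean hits the ancestry target. Over 20 seeds the default
panel stays within 0.03 of the ancestry target and 0.02 of the
heterozygosity target (tested).

Phenotype simulators: additive (y = Normal(μ, σ) + a·g), the
interaction-factor model (focal effect multiplied by 1, (1+I)/2 or I for
partner dosage 0/1/2 — note m(g₂) = 1 + (I−1)g₂/2 is linear in the
partner dosage, so the generative model is exactly a product-term model
with interaction coefficient a(I−1)/2), per-environment phenotypes for
G×E tests, and two-population SNP matrices for F_ST. Simulators emit
complete matrices; `mask_missing` introduces missingness for robustness
tests. Every simulator is bit-reproducible from one root seed per call.

What passing tests on these panels do *not* show: robustness to real
ancestry-calling error, window-size heterogeneity after merging,
segregation distortion hotspots, or trait distributions that are heavy
tailed — the generator produces Gaussian noise and clean calls by design.

## Window construction

Per-SNP diploid ancestry calls collapse to the majority call per window;
an exact tie resolves to the **lower** dosage (toward ancestral) — the
convention is ours, documented and tested, since majority-with-tie is
otherwise ambiguous. Adjacent same-arm windows identical across all RILs
merge (union span, summed SNP counts, cM midpoint of the first and last
members); merging is idempotent and never changes any retained dosage.
Windows with ≥ 90% ancestry bias toward either parent (derived
proportion, heterozygotes counted as half) are excluded from all scans,
as are all-missing windows. The dosage-mean definition of "bias" was
chosen over genotype-class frequencies; the filter is symmetric under
ancestry relabeling.

## Additive scan

Single-marker regression (the maximum-likelihood fit under Gaussian
errors): LOD = (n/2)·log₁₀(RSS₀/RSS₁). Degenerate windows (no genotype
variance, or n < 3) report LOD 0 with a flag; an exact fit reports +inf
with a flag; h² = 1 − 10^(−2·LOD/n) equals the single-window regression
R². The implementation uses per-window sufficient statistics (matrix
products over a missingness mask) and is checked against explicit
least-squares oracles to 1e-9.

Permutations shuffle the phenotype vector jointly against whole genotype
rows, preserving LD; each permutation records the maximum LOD over
non-excluded windows. Genome-wide P is the raw proportion of null maxima
≥ the observed LOD, so P = 0 is attainable and means "beyond every
permutation"; the (r+1)/(n+1) estimator is available behind a flag.

Peak calling: putative QTLs are windows with P strictly below alpha
(default 0.10; boundary ties excluded). Peaks are strict local maxima
over the arm's retained windows, a plateau represented by its first
window. Co-arm peak pairs lacking an intervening window below
(minor LOD − 1.5) lose the minor peak; pairs are processed in descending
minor-LOD order with re-evaluation after each removal, which makes the
outcome order-independent in all configurations we tested. Peaks closer
than 10 cM (genetic midpoints) to a stronger peak are removed; exactly
10 cM apart is retained. The support interval is the maximal contiguous
run of retained windows above peak LOD − 1.5; excluded windows are
transparent to contiguity (they carry no LOD).

Note on h²: the formula is the standard intercross-design conversion of
LOD and n. Published per-QTL h² values from the real panels are not
reproducible from printed LOD and panel n alone (complete-case n per
window differs), so no such values are asserted anywhere.

## Epistasis scan

Interaction LOD = (n/2)·log₁₀(RSS_additive/RSS_full) for
y ~ g₁ + g₂ + g₁g₂ vs y ~ g₁ + g₂, numeric dosages, single-df product
interaction (a categorical 4-df interaction is out of scope). Windows are
ordered canonically before fitting, making the statistic exactly
symmetric in its arguments. A product term collinear with {1, g₁, g₂}
(e.g. no RIL derived at both loci) yields LOD 0 with a degenerate flag.

Partners exclude the focal QTL's support interval and skew-excluded
windows (extending the single-locus exclusion to partners is the
consistent reading). The permutation null fixes the focal window,
shuffles phenotypes, rescans all partners, and keeps the genome-wide max
interaction LOD. The shuffle destroys the focal main effect too —
implemented exactly as specified — which makes the null conservative when
the focal main effect is strong.

Numerics: the public per-pair function uses QR least squares; the batch
scanner used by permutations and power precomputes per-partner 4×4 Gram
matrix pseudo-inverses once and reduces each phenotype to two tall-matrix
contractions (~10³ partners × several hundred RILs per batch runs in
milliseconds). The two routes agree to ~1e-7 and both match an
independent oracle to 1e-9 in tests.

## Meta-analysis

Fisher's combined test: X = −2·Σ ln p ~ χ²(2k). Permutation P-values of
exactly 0 are replaced by 1/(2·n_perm) with a warning. Overlapping QTLs
(correlated traits sharing a region) are collapsed to the top-LOD member
before combination; overlap groups are caller-supplied, never inferred.
The median-removal diagnostic returns the smallest m such that the median
after removing the m lowest P-values reaches 0.5 ("near 0.5" is
formalized as ≥ 0.5, with the full median trajectory returned so users
can apply their own closeness rule); if no m achieves it, m = k − 1 with
an `achieved=False` flag.

## Power designs

*Additive*: per simulation a target window is drawn uniformly from
non-excluded windows (drawing an existing genotype column preserves
realistic skew and heterozygosity, rather than resampling RILs), the
phenotype is Normal(0, 0.75) plus a·g, and the LOD at the target is
scored against the genome-wide max-LOD permutation null built from the
same panel — the faithful analogue of scoring simulations against
empirical-panel permutations. Detection = P ≤ 0.1. Power is reported per
effect a and, secondarily, binned by realized h², because "effect size
0.1" is only a well-posed detection claim on the h² scale (a per-allele
a = 0.1 with σ = 0.75 gives expected LOD far below genome-wide
thresholds, while h² = 0.1 at n = 278 gives LOD ≈ 6.4).

*Epistasis*: the null simulates additive-only phenotypes at the focal
window (1× effect for heterozygotes, 2× for derived homozygotes) and
records the genome-wide max interaction LOD; epistatic simulations apply
the interaction factor at a partner window and use the same max
statistic, matching the null like-for-like (an at-partner statistic is
available behind a flag). P = proportion of null values ≥ the statistic;
power = proportion of simulations with P < 0.05. Default base parameters
a = 0.035, μ = 0.3485, σ = 0.0697 correspond to an intermediate-size
pigmentation QTL.

*Meta*: k interaction P-values are resampled with replacement from the
per-I simulated P pools; reported are the frequencies with which the
Fisher-combined P reaches the observed benchmark (0.763) and the minimum
P undercuts the observed minimum (0.183).

Problem sizes: the acceptance script and test suite use a 1,000-
permutation null with 600 additive simulations, and 500 null / 250
epistatic interaction simulations — sizes chosen so binomial standard
errors on the reported power are ≤ ~0.03 while the whole computation
stays interactive (seconds). The focal/partner pair for the epistasis
design is fixed deterministically as the central windows of arms 2L and
3R: unlinked, with genotype distributions representative of the panel
average. Same-arm (linked) partners near the focal window have sharply
reduced interaction power because the product term is nearly collinear
with the main effects — one reason the scan excludes the focal support
interval.

## G×E and F_ST

The G×E test is the fixed-effects model y ~ g + env + g:env with numeric
dosage and a 0/1 environment indicator (environments in sorted label
order), interaction tested by model-comparison F; RILs measured in both
environments are independent records (no RIL random effect). More than
two environments use a categorical-environment model with a joint
interaction F test. Fits go through statsmodels OLS; the F statistic is
oracle-checked against an explicit RSS comparison.

F_ST uses the Hudson estimator (unbiased numerator; slightly negative
expected per-SNP values at equal frequencies are normal). Window-wide
F_ST is the ratio of summed numerators to summed denominators (not the
mean of ratios); max-SNP F_ST is the largest per-SNP ratio among SNPs
with positive denominator. Reported values are clipped to [0, 1] with raw
values retained. Outlier flagging takes the top 1% per arm and statistic
among windows whose midpoint lies in a high-recombination interval
(defaults shipped for the five fly arms, ~0.5 cM/Mb cutoff); ties at the
threshold are all flagged, and arms with too few eligible windows flag at
least the maximum, with a warning. A third, externally computed statistic
(e.g. a haplotype-differentiation score) can join the any-of union via
`extra_statistics`.

## Known limitations

- The tract simulator has no segregation distortion, no X-specific
  inheritance, and uniform window sizes; its linkage decay is exponential
  in cM rather than pedigree-derived.
- The interaction test is single-df additive-by-additive; dominance or
  categorical epistasis patterns that leave the product term orthogonal
  will be missed by design.
- Permutation nulls assume exchangeable phenotypes (no family or batch
  structure among RILs).
- The G×E model treats repeated measurements of a RIL across
  environments as independent; with strong line effects the interaction
  test is anticonservative.
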