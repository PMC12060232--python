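# rilqtl

QTL mapping, epistasis scanning and power analysis for biparental
recombinant-inbred-line (RIL) panels genotyped as **ancestry windows** —
the design used to map adaptive trait differences between derived and
ancestral *Drosophila melanogaster* populations (Ethiopia- and
France-derived crosses against Zambia). Each RIL is a mosaic of the two
parental ancestries, summarized in ~19 kb nonoverlapping windows as an
ancestry dosage: 0 (ancestral homozygote), 1 (heterozygote), 2 (derived
homozygote).

The package is aimed at researchers who map quantitative traits in such
panels and want every stage — from window genotypes to the epistasis
meta-analysis — as tested, reusable, seed-reproducible code, with a
synthetic-panel generator so the whole pipeline runs without any external
data.

## What it computes

**Additive genome scan.** Per window, a Gaussian linear model
*y* = *b*₀ + *b·g* is fit by least squares and compared with the
intercept-only model:

LOD = (*n*/2) · log₁₀(RSS₀ / RSS₁)

Genome-wide significance uses the permutation distribution of the maximum
LOD (trait values shuffled against whole genotype rows). Windows with
≥ 90% ancestry bias toward either parent are excluded. Peaks require
genome-wide *P* < 0.10, local-maximum status, a 1.5-LOD valley separating
co-arm peaks, and ≥ 10 cM separation from stronger peaks; the support
interval is the contiguous run of windows above peak LOD − 1.5. QTL
heritability is *h*² = 1 − 10^(−2·LOD/*n*).

**Epistasis scan.** For each focal QTL, every window outside its support
interval is tested with the interaction likelihood ratio of
*y* ~ *g*₁ + *g*₂ + *g*₁·*g*₂ against *y* ~ *g*₁ + *g*₂ (single-df
product term). The null fixes the focal window, shuffles phenotypes, and
keeps the genome-wide maximum interaction LOD per permutation.

**Meta-analysis.** Per-QTL interaction *P*-values are combined with
Fisher's method (−2·Σ ln *p* ~ χ²(2*k*)); overlapping QTLs contribute
only their top-LOD member. A median-removal diagnostic reports how many
of the smallest *P*-values would need dropping for the median to reach
0.5.

**Power simulation.** Additive power across an effect grid (phenotype
Normal(0, 0.75) plus *a*·dosage at a randomly drawn window, scored
against the max-LOD null, binned by realized *h*²); epistasis power under
the interaction-factor model — the focal effect (*a* = 0.035,
*μ* = 0.3485, *σ* = 0.0697 by default) is multiplied by 1, (1+*I*)/2 or
*I* according to partner dosage 0/1/2, covering sign (*I* < 0), masking
(*I* = 0), diminishing-returns (0 < *I* < 1) and positive (*I* > 1)
epistasis; and meta-analysis power by resampling *k* *P*-values.

**Also included:** window summarization from per-SNP ancestry calls
(majority call, identical-adjacent merging, skew flags), reaction norms
and genotype-by-environment F tests, Hudson *F*_ST (window-wide and
max-SNP) with per-arm top-1% outlier flagging inside high-recombination
regions, and a synthetic panel generator calibrated to the real panels
(278–328 RILs, 67.8%/77.9% derived ancestry, 8.7%/5.3% residual window
heterozygosity, megabase-scale ancestry tracts over 5 chromosome arms).

## Worked example

```python
from rilqtl.simulate import PanelConfig, simulate_panel, AdditiveSimConfig, \
    simulate_additive_phenotype
from rilqtl.windows import flag_skewed
from rilqtl.scan import scan_additive, permutation_null, genomewide_p, call_qtl_peaks
from rilqtl.epistasis import interaction_scan, interaction_null, interaction_p

matrix, wmap = simulate_panel(PanelConfig(seed=1))      # 278 RILs x 1,030 windows
summary = flag_skewed(matrix)                           # ancestry-skew exclusions

# plant a QTL of effect 0.3 per derived allele at window 2R_w0089
y = simulate_additive_phenotype(
    matrix, AdditiveSimConfig(mu=0.0, sigma=0.75, a=0.3,
                              target_window="2R_w0089", seed=2))

null = permutation_null(matrix, y, summary, n_perm=1000, seed=3)
scan = genomewide_p(scan_additive(matrix, y, summary), null)
calls = call_qtl_peaks(scan, wmap, alpha=0.10, lod_drop=1.5, min_sep_cM=10)

q = calls[0]
print(f"QTL at {q.peak_window} (arm {q.arm}): LOD={q.lod:.2f}, P={q.p}, "
      f"b={q.b:.3f}, h2={q.h2:.3f}, CI={q.ci_windows[0]}..{q.ci_windows[-1]}")

escan = interaction_scan(matrix, y, q, summary)
enull = interaction_null(matrix, y, q, summary, n_perm=1000, seed=4)
print(f"max interaction LOD {escan.max_lod:.2f} at {escan.max_partner}, "
      f"genome-wide P = {interaction_p(escan, enull)}")
```

Output:

```
QTL at 2R_w0089 (arm 2R): LOD=6.53, P=0.0, b=0.295, h2=0.103, CI=2R_w0088..2R_w0090
max interaction LOD 1.54 at 3L_w0051, genome-wide P = 0.83
```

The scan recovers the planted window exactly: the estimated per-allele
effect 0.295 matches the generative 0.3, the genome-wide *P* of 0 means
the peak LOD beat all 1,000 permutation maxima, and *h*² ≈ 0.10 says the
QTL explains ~10% of phenotypic variance. The epistasis scan finds no
partner (the phenotype is purely additive): the best interaction LOD
anywhere in the genome is unremarkable under the permutation null
(*P* = 0.83).

The same stages are available as a CLI (`rilqtl simulate / windows /
scan / epistasis / meta / power-qtl / power-epi / gxe / fst / run`); the
`run` subcommand executes scan → peaks → epistasis → meta end to end and
writes a manifest with seeds, input checksums and timings.

The bundled catalog of 14 empirical QTLs (`rilqtl.datasets`) reproduces
the published meta-analysis: the 13 nonoverlapping interaction
*P*-values give a Fisher combined *P* of 0.763, with minimum 0.183 —
no evidence of epistasis involving these adaptive loci.

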