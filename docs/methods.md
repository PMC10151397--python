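# Methods

This note documents the statistical models, conventions and numerical
choices implemented in `crypteqtl`, and what the synthetic-data tests do
and do not establish about real data.

## Data model

Expression is a spots × samples matrix of log2-normalized intensities;
each sample carries a strain id and a two-level treatment label.
Genotypes are strains × markers biallelic calls (reference/alternative
parent, missing allowed), with a marker map giving chromosome and 1-based
bp position, strictly increasing within a chromosome. All genomic
intervals are half-open `[start, start + width)` except eQTL confidence
intervals and trans-band overlap checks, which use closed intervals so
that a boundary touch counts as overlap. Gene positions for cis/trans
classification are the annotated gene start.

## Preprocessing

Quantile normalization forces every sample onto the across-sample mean
order statistics; ties receive the mean of the tied reference quantiles,
and the operation is idempotent. The log2-ratio transform is
mean-centering in log space, `R_ij = y_ij − mean_j(y_i·)` — equivalent to
the ratio to the per-spot geometric mean when inputs are log2, which is
the convention adopted here (inputs are taken as log2 throughout; a
linear-scale arithmetic mean would differ only by Jensen-gap terms and
requires positive intensities). PCA standardizes spots to unit variance
across samples (zero-variance spots dropped) and decomposes by SVD;
variance fractions are eigenvalue shares of the total (= number of
retained spots).

## Differential expression

Per spot, OLS of expression on the treatment indicator; the slope t test
equals the pooled two-sample t test. Fold change is the difference of
treatment means in log2 units (perturbed − control). Bonferroni
multiplicity is the number of spots actually tested, not a fixed array
size, so the procedure is correct on arbitrary inputs. Selection uses
strict inequalities (Padj < 0.05, |lfc| > 2). Tests are two-sided; genes
represented by several spots are called DE if any spot passes.

## Transcriptional age

The ruler is built by per-spot OLS of expression on sample age within the
41.5–72 h window (≥ 3 distinct time points required); spots are retained
when −log10(P) > 6 **and** |slope| > 0.1 per hour (both strict), storing
the slope and the fitted expression at the window midpoint (56.75 h).
"log10(P) > 6" is read as a −log10 criterion, the only direction that
makes it a significance filter. A sample's age minimizes
Σᵢ (yᵢ − (aᵢ + bᵢ(t − mid)))², giving the closed form
t̂ = mid + Σ bᵢ(yᵢ − aᵢ)/Σ bᵢ²; ruler spots are unweighted (weighting by
fit significance was considered and rejected for simplicity — with the
strict inclusion filters all retained slopes are precisely estimated).
Relative age is the rank-based inverse-normal transform
z = Φ⁻¹((rank − ½)/n), which guarantees a standard-normal score
regardless of the age distribution; the plain (x − μ)/σ z-score is
available via `method="zscore"`.

## eQTL mapping and thresholds

The scan regresses each spot on each marker's 0/1 allele indicator.
It is computed from the spot × marker correlation matrix,
t = r·√(df/(1 − r²)) with df = n − 2, mathematically identical to the
OLS slope test and to the pooled two-group t test (verified against
scipy's implementation to 1e-9 in the suite). Samples missing a call at
a marker are dropped from that marker only; markers left with fewer than
2 strains per class are assigned p = 1 with a warning. p-values are
floored at 1e-300 before −log10.

Genome-wide thresholds: expression columns are permuted across strains
(whole-column shuffles, preserving spot–spot correlation), the scan is
repeated (default 10 permutations), and over a −log10(p) grid of step 0.1
the mean permuted discovery count FDS(T) is compared with the real count
RDS(T), a spot counting as discovered when any marker passes T. The
chosen threshold is the smallest T with FDS/RDS ≤ q (default q = 0.05).
An optional multiplicative factor (m₀/m)·log(m), with m the spots tested
and m₀ = m − RDS(T) the estimated true nulls, is available via
`corrected=True`; the plain ratio is the default because it is the
defensible core of the permutation-FDR criterion, and both code paths are
tested. With no true signal the criterion has no qualifying threshold and
the function raises.

Peaks: at most one per chromosome (the maximal marker above threshold;
ties to the leftmost). No within-chromosome multi-peak splitting is
attempted — linked secondary peaks are not separable at these panel
sizes. Confidence intervals extend marker-by-marker from the peak while
−log10(p) ≥ peak − 1.5 and never cross a chromosome boundary. An eQTL is
cis when the peak is on the gene's chromosome within 1 Mb (inclusive),
else trans. Variance explained is the one-way ANOVA R² at the peak
marker. Cross-dataset comparison: a gene is shared-cis when cis in both
sets, shared-trans when trans CIs intersect on the same chromosome.

## Trans-band hotspots

The genome is tiled with ceil(length/width) half-open 0.5 Mb bins per
chromosome (203 bins for WS220 lengths I 15,072,423; II 15,279,345; III
13,783,700; IV 17,493,793; V 20,924,149; X 17,718,866). Trans-eQTL are
counted per bin at spot level (gene ids are carried alongside). The null
rate λ is the dataset's own mean count per bin; a bin is a trans-band
when the inclusive Poisson upper tail P(X ≥ count) < 10⁻⁴. Adjacent
significant bins are reported separately (bin-resolution bands).

## Power analysis

For every polymorphic marker, phenotypes y = b·x + ε with ε ~ N(0,1) and
b = √(v/(1−v))/sd(x), the unique scaling making the population R² at the
causal marker equal v "on top of" unit noise. Each replicate runs a full
genome scan. Detection conventions:

- `"causal"` (default): the causal marker itself exceeds the threshold.
  This is the direct reading of a per-marker power analysis; its power
  equals the closed-form noncentral-t power with noncentrality
  δ = √(v/(1−v))·√n (independent of allele frequency), which the suite
  verifies. For v = 0.35 at −log10(P) > 3.9 it gives ≈ 62% (n = 39) and
  ≈ 76% (n = 46).
- `"window"`: any marker within 1 Mb of the causal locus passes —
  slightly anti-conservative (multiple correlated chances).
- `"peak"`: a called chromosome peak above threshold lies within 1 Mb —
  strictest, because noise can displace the peak to a correlated marker
  outside the window; measured ≈ 4–6 points below the causal convention
  at v = 0.35.

False positives are passing called peaks farther than the window from the
causal marker (other chromosomes included); location error is the
distance from the causal marker to the in-window passing peak; the effect
ratio is the peak-estimate over the true b, upward-biased at low power
(winner's curse) and ≈ 1 for v ≥ 0.5.

## Enrichment

Upper-tail hypergeometric tests of a query gene set against category
tables, after excluding categories of size ≤ 3 or query overlap ≤ 2
(strict filters applied before testing); Bonferroni multiplicity is the
number of categories that pass the filters. When no universe is declared
it defaults to the union of category members plus the query — the least
presumptive choice when the assay's true background is unknown.

## Synthetic data

The generator emulates a two-parent RIL panel: per strain and chromosome
a Poisson(rate) crossover count with uniform bp breakpoints, alternating
fixed parental blocks from a random starting parent — fully inbred lines,
no heterozygosity, no missing calls. The default map spreads 729 markers
over the six WS220 chromosomes proportionally to length; the default rate
is 1.5 crossovers per chromosome, giving realistic block structure and
near-0.5 allele frequencies. Expression adds, per spot: a Gaussian
baseline, planted cis/trans marker effects, a treatment shift, a linear
age term around the 56.75 h reference, and N(0, noise_sd²) noise
(noise_sd = 1 by default, matching the power-analysis convention); one
sample per strain × treatment level. A truth table records every planted
signal once.

What the generator does **not** emulate: probe-level effects and
cross-hybridization, dye/batch structure, recombination-rate
heterogeneity along chromosomes (crossovers are uniform in bp), linkage
between planted signals and genetic background beyond the marker map, and
non-Gaussian expression noise. Passing tests therefore demonstrate the
statistical machinery (type-I control, FDR control against planted truth,
recovery and calibration) under idealized conditions, not robustness to
microarray artefacts.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds exposed at
every API entry point; identical seeds give identical outputs. The
end-to-end checks use panels of 39–50 strains, 150–729 markers, and
200–2,000+ replicates per estimate — sizes at which Monte-Carlo standard
errors are comfortably below the tolerances being asserted while the full
suite runs in well under a minute per module. The headline power
recomputation uses 3 noise replicates per marker × 729 markers = 2,187
genome scans per panel size.

## Known limitations

- One peak per chromosome: spots with two linked eQTL on one chromosome
  are reported as a single peak.
- The permutation-FDR criterion can select a threshold on datasets where
  the real scan's top spot beats all permutations by chance; with ≥ 10
  permutations and realistic spot counts this is rare, and the pure-noise
  error path is tested.
- `estimate_age` extrapolates linearly outside the 41.5–72 h window;
  estimates far outside it are not meaningful.
- Parental strains are not distinguished from RILs; if parental samples
  are present they enter mapping unless filtered by the caller (RILs-only
  is the recommended and default usage).
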