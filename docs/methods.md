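# Methods

This package reimplements, as desk-scale tested code, an integrated analysis
of phenotypic and genetic variation in the *Mantella aurantiaca* /
*M. crocea* / *M. milotympanum* species complex: image-derived dorsal color
and side/ventral pattern, de novo RAD-seq locus assembly with
genotype-likelihood population genomics, and permutation tests relating the
resulting distance matrices. This note records the models, the defaults and
their justification, and the choices made where the underlying protocol left
the design open.

## Color quantification (`imagecal`)

Photographs are single-point calibrated: each channel is scaled linearly so
the mean of the 18%-reflectance gray-standard patch equals 0.18. A saturated
standard is rejected rather than corrected, since a clipped patch carries no
usable scale information. Mean (R, G, B) reflectance over the dorsal regions
of interest (the 3×3 mm square and 3×1 mm rectangle are pooled into one pixel
sample; a per-ROI mean is available by passing masks separately) is mapped to
an opponent color space:

- x = (R − G)/(R + G)  (red–green channel)
- y = (G − B)/(G + B)  (blue–green channel)
- luminance = R (untransformed reflectance)
- chroma = √(x² + y²), hue = atan2(y, x) in degrees on [0, 360)

Hue at chroma 0 is undefined and is reported as missing, never imputed as 0.
The dorsal-color distance matrix is the Euclidean distance over (x, y) only;
luminance is excluded because achromatic signals are processed separately in
vertebrate vision. Luminance here is calibrated reflectance R (the
"untransformed R" of the field protocol is ambiguous between camera-native
and normalized values; normalized is the only choice consistent with
cross-photograph comparison).

## Granularity pattern analysis (`granularity`)

Surfaces are first resampled to a common physical resolution (side 19 px/mm,
ventral 18.6 px/mm; bilinear for pixels, nearest for masks). The masked
luminance image is embedded in a mean-padded square power-of-two canvas and
decomposed by FFT bandpass filtering on a geometric series of scales
starting at 2 px and growing by √2 (16 levels under a 430 px cap for the
side surface, 14 under 193 px for the ventral surface).

Band k is an ideal (hard-edged) annulus passing wavelengths [s_k, s_k·√2).
Adjacent bands tile the spectrum exactly, which gives a Parseval identity:
for content inside the covered band, the squared band energies sum to the
masked variance (tested at 5%). Bands are labeled by their **lower**
wavelength edge. The labeling convention was genuinely open; the lower-edge
choice is physically motivated — a marking element of size s is half a
spatial period, so a field of spots of diameter d concentrates energy at
wavelengths ≈ 1.4 d, i.e. in the band labeled within one series step of d —
and it keeps a sinusoid of wavelength λ in the band labeled λ. A smooth
Gaussian band-edge option (`edge="gaussian"`, width in octaves) is provided
but is not the default because it breaks the tiling identity.

Band "energy" is the standard deviation of the filtered image inside the
mask (the s.d./sum-of-absolute-values choice was open; s.d. gives the
Parseval property). Summary statistics, with the definitions the toolbox
literature uses but does not formalize:

- pattern contrast = Σ_k energy_k (total spectral energy),
- pattern diversity = normalized Shannon entropy of energy proportions
  (0 = single-scale pattern, 1 = even spread),
- luminance contrast = s.d. of the masked, unfiltered luminance,
- dominant scale = scale of the argmax band.

Pattern distance between individuals is the total-variation distance
(½·L1 of frequency-normalized histograms) between their 95-bin luminance
histograms over [0, 100%] reflectance: bounded in [0, 1], a metric, and
sensitive to the discrete light/dark patches that characterize these
patterns. The underlying calculator publishes no formula; total variation is
the minimal distribution-difference measure with these properties.

## De novo RAD pipeline (`radloci`)

Reads are demultiplexed on inline barcodes (one mismatch allowed; barcode
sets must be pairwise Hamming ≥ 3 so assignment is unambiguous), checked for
the SbfI cut-site remnant TGCAGG at the read start (one mismatch), exact
duplicates removed (first occurrence kept), and reads under 50 bp dropped.
Failing reads are counted, not raised — QC semantics.

Within each individual, reads are clustered greedily, longest-first, at 95%
ungapped end-anchored identity (matches over the shared prefix). Because all
reads are anchored at the cut site and no indels are modeled, gapped
alignment adds nothing; this reproduces cd-hit-style clustering in pure
code. Clusters need ≥ 2 supporting reads; the seed is the marker
representative. Markers are masked for homopolymers (≥ 10 bases) and
dinucleotide repeats (≥ 6 units) with Ns — a parameterized stand-in for
repeat-library masking — and dropped when Ns exceed 30% (exactly 30% is
retained). Within-individual paralogs are removed by all-vs-all
self-matching at 90% identity over ≥ 50 bases; both members of a hit are
removed, since a collapsed duplicated locus cannot be genotyped either way.
The cross-individual pseudo-reference keeps clusters (90% identity) whose
representative is ≥ 50 nt and whose members span ≥ 60% of individuals,
counted by retained markers. Catalog membership replaces read mapping:
per-site base counts come column-wise from each member marker's supporting
reads against the representative.

Site filters, each independent: markers with > 2 alleles at any site are
dropped (an allele is "observed" above a noise floor of ≥ 2 reads and ≥ 10%
of pooled site depth); sites failing a one-tailed Hardy–Weinberg exact test
for heterozygote **excess** at p ≤ 1e−4 are dropped (excess heterozygosity
is the collapsed-paralog signature, which is what this filter exists to
catch in RAD data); sites outside the 1st–99th percentile of pooled depth
are dropped; and sites covered ≥ 3× in fewer than 60% of individuals are
excluded downstream. The exact test uses Levene's conditional distribution
of heterozygote counts given allele counts, computed in log space; it is
verified against an exact-rational enumeration to 1e−12.

## Genotype-likelihood population genomics (`popgen`)

Low coverage (1.8–13.9×, mean 5.4×) makes hard genotype calls unreliable,
so analyses work from genotype likelihoods under a biallelic per-read error
model with uniform error e: a read reports the major allele with probability
(1 − g/2)(1 − e) + (g/2)(e/3) given g minor copies. Per-site minor-allele
frequencies are maximized by 1-D EM; variable sites are called with a
likelihood-ratio test (2(ℓ(p̂) − ℓ(0)) against χ²₁, p < 1e−6) where ≥ 80% of
individuals have ≥ 3× depth; genotype posteriors use an HWE prior at p̂, and
hard calls are made only above 0.95 posterior.

Downstream: PCA of the covariance of standardized posterior-mean genotypes
(sites fixed at p̂ ∈ {0, 1} excluded); expected-mismatch genetic distance
D_ij = mean over shared sites of Σ P(g)P(g′)|g − g′|/2 (the uncorrected
expected-p-distance form, as no evolutionary-model correction was
specified); and Hudson pairwise F_ST as a ratio of averages on
posterior-mean allele frequencies with haploid sample sizes 2n — chosen over
SFS-based machinery because it is desk-scale, unbiased for small samples,
and estimates the Balding–Nichols divergence parameter directly (verified at
F_ST 0.2 ± 0.03 with 2,000 sites).

Admixture is estimated by EM over individual ancestry proportions Q and
cluster allele frequencies F under HWE at h_is = Σ_k Q_ik F_ks, from the
genotype likelihoods (the NGSadmix model). Allele copies are fractionally
assigned to clusters in the E-step; the log-likelihood is asserted
non-decreasing every iteration, and frequencies are clamped to
[1e−5, 1 − 1e−5]. K = 1 reduces exactly to the minor-allele-frequency model.
Label switching between replicates/truth is resolved by Hungarian matching
on L1 cost.

The number of clusters is chosen by the Evanno ΔK rule:
ΔK = mean_r |L_r(K+1) − 2 L_r(K) + L_r(K−1)| / sd(L(K)) over replicates
(paired by replicate index), maximized over interior K, ties to the smallest
K. ΔK is undefined at the endpoints — K = 1 can never be selected, an
inherent limitation of the method — and zero replicate spread raises rather
than being silently patched. ΔK behaves as designed in the balanced
multi-deme setting: with three equal-sized diverged populations it selects
K = 3 by three orders of magnitude of ΔK; with strongly unequal cluster
sizes the first split dominates the likelihood gain and ΔK prefers K = 2,
which is a documented property of the method, not of this implementation.
The model-choice analyses therefore use balanced unadmixed subsets
(`simdata.balanced_cluster_subset`).

Populations are assigned to the cluster contributing > 50% of their mean
ancestry; without a majority they are reported unassigned.

## Matrix tests (`matrixtests`)

Geographic distance is the haversine great-circle distance (Earth radius
6371.0 km). The Mantel statistic is the Pearson correlation of vectorized
upper triangles; the null permutes rows and columns of one matrix together.
p-values use the add-one convention (1 + exceedances)/(1 + permutations), so
p is never 0 and its floor is 1/(n_perm + 1); an exhaustive mode enumerates
all n! permutations. The default tail is one-sided "greater", matching the
directional hypotheses (and vegan's default); two-sided is a flag. The
partial Mantel statistic is the first-order partial correlation r_XY·Z,
identically the correlation of the X-on-Z and Y-on-Z triangle residuals; the
null permutes the Y-residual matrix (the Legendre residual-permutation
variant — the specific variant was not recorded, so this choice is
documented here). Partial Mantel tests inflate type-I error under spatial
autocorrelation; the integrated report is intended to be read alongside the
plain pairwise tests, and no multiple-testing correction is applied by
default (a Holm option exists on the report frame if wanted, via
`scipy.stats.false_discovery_control` or statsmodels on the `p` column).

The integrated within-cluster report tests genetic distance against dorsal
color, geography, side pattern and ventral pattern per genetic cluster
(clusters from the > 50% population-ancestry rule; per-individual grouping
is by population, since an individual-level assignment rule was not
specified), controls for geography in partial tests, flags the maximum-r
variable per cluster, excludes the two unusable-photograph individuals, and
skips groups smaller than 4 with a warning.

## Synthetic data (`simdata`) — what it emulates and what it does not

The manifest fixture reproduces the study design exactly: 88 individuals in
16 populations (11 aurantiaca in 2, 34 crocea in 6, 19 milotympanum in 3,
24 cf. milotympanum in 5), two individuals (ABNK09, RAN11) flagged as
lacking usable photographs, and a photographed sex composition of 58 M /
26 F / 2 juveniles. Per-population sample sizes within each taxon are not
published, so individuals are distributed evenly over each taxon's
populations. Coordinates are plausible central-eastern Madagascar localities
arranged so geographic and genetic structure covary.

Genetics: three ancestral clusters under a Balding–Nichols model
(cluster frequencies Beta-distributed around shared ancestral frequencies at
a target F_ST, default 0.2 — standard, and it makes cluster separation
tunable for model-choice experiments). Cluster A holds the two outlying
"green crocea" populations, B the remaining crocea plus both aurantiaca
populations, C all milotympanum; cf. milotympanum populations are admixed
B/C (30–45% B). Per-individual mean depths are gamma-distributed, clipped to
the observed 1.8–13.9× range and centered on 5.4×; base error is 1%.

Reads are barcode + TGCAGG + locus with Poisson per-locus depth, i.i.d.
errors, and a uniform 0–8 bp 3′ truncation emulating per-read quality
trimming. The truncation matters structurally: without it, error-free reads
of a homozygous locus are byte-identical and exact-duplicate removal would
destroy genuine coverage, which is not how trimmed real reads behave.
Injected PCR duplicates are exact copies; injected paralogs default to 93%
identity — between the 95% within-individual clustering threshold and the
90% self-match threshold, so they appear as separate markers and are caught
by the paralog filter. Paralogs more similar than the clustering threshold
collapse into one cluster at the clustering stage and manifest as
heterozygote excess instead, which the HWE filter targets.

Images contain a gray patch at 0.18 × a random illumination factor, a body
whose base color interpolates between cluster-determined and
cluster-independent under a coupling parameter in [0, 1] (so phenotypes can
track genetics fully, partially, or not at all), and dark circular spots of
configured diameter on the side and ventral regions. Everything is a pure
function of the scenario seed.

Not emulated: read quality scores beyond a constant, indels, library-prep
artifacts beyond exact duplicates, camera spectral sensitivity, lighting
gradients or glare, and body-shape variation. Passing tests therefore show
that the algorithms recover known structure under the stated statistical
model — not that they are robust to optical or molecular artifacts absent
from that model.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down designs chosen to keep each result
statistically decisive: 500 sites and 36 individuals (12 per cluster) for
model choice over K = 1–5 with ten EM replicates; 300 sites over all 88
individuals for the integrated report; 2,000 sites and 2 × 25 individuals
for the F_ST check; 1,000 null simulations at 199 permutations for Mantel
type-I calibration. EM runs to relative tolerance 1e−6–1e−7 with a 400–500
iteration cap; the per-site frequency EM to 1e−10. Every stochastic routine
takes an explicit seed, and replicate seeds are derived deterministically.

Known limitations: the greedy clusterer is order-dependent in principle
(stable and deterministic for a fixed input order; on clean data shuffling
does not change the catalog); the Evanno rule cannot select K = 1 and is
unreliable for strongly unequal clusters (above); ideal bandpass annuli
ring on sharp edges, which is immaterial for band s.d. statistics but makes
individual filtered images unsuitable for display; and Hudson F_ST on
posterior-mean frequencies slightly attenuates at very low depth, where
posteriors shrink toward the prior.
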