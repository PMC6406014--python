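# radpheno

Integrated analysis of color/pattern phenotypes and RAD-seq population
structure in Malagasy poison frogs (*Mantella aurantiaca*, *M. crocea*,
*M. milotympanum* and intermediate *M. cf. milotympanum* populations).

In this species complex, dorsal coloration ranges from red to green and
side/ventral patterning varies dramatically within and among 16 sampled
populations, while species boundaries are unresolved. The analytical
question is how phenotypic, genetic and geographic distances relate within
each major genetic cluster: whether color variation tracks genetic
structure, geography, or neither. This package is aimed at evolutionary
biologists working on polymorphic/polytypic (often aposematic) systems who
want the full chain — from calibrated photographs and raw reads to the
matrix-regression table — as reusable, tested code.

## What it computes

**Color** (`imagecal`): photographs calibrated against an 18% gray standard
are reduced to a two-dimensional opponent color space,
x = (R−G)/(R+G), y = (G−B)/(G+B), with luminance = R, chroma = √(x²+y²) and
hue = atan2(y, x); dorsal-color distance is Euclidean over (x, y).

**Pattern** (`granularity`): FFT-bandpass granularity analysis on a √2
geometric scale series (16 levels to 430 px for side surfaces, 14 to 193 px
for ventral) yields a per-scale energy spectrum with pattern contrast,
pattern diversity, luminance contrast and dominant marking scale; pairwise
pattern distance is the total-variation distance between 95-bin luminance
histograms.

**RAD loci** (`radloci`): barcode demultiplexing with cut-site checking,
exact-duplicate removal, per-individual 95%-identity clustering into
markers (≥2 reads), low-complexity masking, self-match paralog removal, a
cross-individual 90%-identity pseudo-reference (loci ≥50 nt shared by ≥60%
of individuals), and per-site filters including a one-tailed
Hardy–Weinberg exact test for heterozygote excess.

**Population genomics** (`popgen`): genotype likelihoods under a per-read
error model, ML allele frequencies with likelihood-ratio SNP calling, PCA
of the posterior-genotype covariance, expected-mismatch genetic distances,
Hudson pairwise F_ST, NGSadmix-style admixture EM (ancestry proportions Q,
cluster frequencies F), and Evanno ΔK model choice,
ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)).

**Integration** (`matrixtests`): haversine geographic distances and
Mantel / partial Mantel permutation tests (Pearson r on upper triangles,
999 permutations by default) relating genetic distance to dorsal color,
geography, side and ventral pattern within each genetic cluster.

**Synthetic data** (`simdata`): the field data are not bundled, so a
first-class generator reproduces the study's structure — the 88-frog /
16-population manifest (with the two excluded-photograph individuals),
Balding–Nichols three-cluster genetics with admixed populations, 1.8–13.9×
coverage averaging 5.4×, and photographs whose color and spotting covary
with cluster ancestry to a configurable degree — with truth tables for
every stage.

## Worked example

```python
import numpy as np
from radpheno import simdata, imagecal, granularity, popgen

sc = simdata.SimScenario(seed=1, n_sites=500)

# phenotype of one frog
img = simdata.simulate_frog_image(sc, "MILO01")
cal = imagecal.normalize_image(img.raw, img.gray_patch,
                               px_per_mm=img.px_per_mm, roi_masks=img.roi_masks)
point = imagecal.rgb_to_colorpoint(
    *imagecal.roi_mean_rgb(cal, ["dorsal_square", "dorsal_rect"]))
print(f"MILO01 dorsal: chroma={point.chroma:.3f} hue={point.hue:.1f} deg "
      f"luminance={point.luminance:.3f}")

spec = granularity.bandpass_energy(cal.pixels[:, :, 0], cal.roi_masks["ventral"],
                                   granularity.build_scale_series(128))
print(f"ventral pattern: contrast={spec.pattern_contrast:.3f} "
      f"diversity={spec.pattern_diversity:.2f} dominant scale={spec.dominant_scale:.1f} px")

# genetics: admixture on a balanced three-cluster subset
subset = simdata.balanced_cluster_subset(sc, per_cluster=12)
pile = simdata.simulate_pileup(sc, individuals=subset)
gl = popgen.compute_gl(pile.major_counts, pile.minor_counts, 0.01, pile.other_counts)
fit = popgen.admixture_em(gl, K=3, seed=0)
perm = popgen.match_cluster_labels(fit.Q, pile.q_true)
print(f"K=3 loglik={fit.loglik:.1f}; mean |Q - Q_true| = "
      f"{np.abs(fit.Q[:, perm] - pile.q_true).mean():.3f}")

snp = popgen.estimate_maf_and_call_snps(gl)
fst = popgen.pairwise_fst(snp.expected_genotypes, pile.populations, pile.depth)
print(f"pairwise FST between cluster-A and cluster-C populations: "
      f"{fst.loc['ABNK', 'MILO']:.2f}")
```

Output:

```
MILO01 dorsal: chroma=0.758 hue=39.7 deg luminance=0.597
ventral pattern: contrast=0.493 diversity=0.89 dominant scale=11.3 px
K=3 loglik=-34987.8; mean |Q - Q_true| = 0.016
pairwise FST between cluster-A and cluster-C populations: 0.13
```

The red frog's color point sits at high chroma between the +x (red–green)
and +y (blue–green) axes; its ventral spotting (8 px spots) is localized one
scale step above the spot diameter with high spectral diversity; admixture
EM recovers the true ancestry matrix to within 2%, and the two most
diverged population pairs show substantial allele-frequency differentiation.

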