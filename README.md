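# taproot

Digital phenotyping of single, non-branching storage roots (carrot-style
taproots), and quantitative-genetic analysis of the traits it measures.

Market class in carrot — Imperator, Nantes, Danvers, Chantenay,
Parisienne — is defined by quantitative shape features: root length and
width, the curvature of the shoulder at the crown, the fill of the tip,
and how far along its length a root maintains its maximum width. These
are tedious to measure by hand and subjective to score by eye. `taproot`
extracts them from binary masks of photographed roots, and turns
replicated half-diallel trials of those phenotypes into estimates of
combining-ability variance, additive and dominance variance, and
heritability.

## What it computes

**Image side.** From an RGB photo (root on a contrasting background) or a
ready-made binary mask:

1. *Masking* — grayscale → bilateral filter → binary threshold → largest
   connected component, holes filled. Physical scale comes from the pixel
   length of a 100 mm scale bar encoded in the filename
   (`{genotype}_{rootid}_{barpx}.png`).
2. *Midline and widths* — the root tip is found by iterating a curvature
   argmax over shrinking contour segments, with curvature
   K = (x′y″ − y′x″)/((x′)² + (y′)²)^{3/2} from local parametric spline
   fits; the midline is walked from tip to shoulder centre along the ridge
   of the Gaussian-smoothed Euclidean distance transform; widths are
   sampled normal to the midline tangent, which keeps slices single even
   where a tip curls back. Stacking the centred widths straightens the root.
3. *De-tipping* — a random-forest scorer trained on labelled width
   profiles removes the thin residual taproot below the storage root.
4. *Traits* — length, maximum and decile widths, aspect ratio, root size
   (mask area), tip angle, shoulder hull area; plus population shape
   scores: **root fill** (PC1 of 1000-point length- and width-normalised
   profiles) and shoulder/tip curvature PC1 (PCA of K over the 50 contour
   points around the crown and the tip).

**Genetics side.** For a half-diallel (all p(p−1)/2 crosses of p parents,
no selfs, no reciprocals), Griffing's Method IV, Model I:

    y_ijk = μ + g_i + g_j + s_ij + ε_ijk

with expected mean squares EMS_GCA = Vε + V_SCA + (p−2)·V_GCA and
EMS_SCA = Vε + V_SCA, then V_A = 4/(1+F)·V_GCA, V_D = 4/(1+F)²·V_SCA,
V_G = V_A + V_D, H² = V_G/(V_G + Vε/r), h² = V_A/(V_G + Vε/r), and
Baker's ratio 2·MS_GCA/(2·MS_GCA + MS_SCA).

A synthetic-root renderer and a diallel simulator (`taproot.synth`)
provide exact ground truth, so every stage is testable without any image
download.

## Worked example

`examples/diallel_heritability.py` simulates an eight-parent half-diallel
(28 crosses × 2 replicate plots × 15 roots) with known variance
components σ²_GCA = 25, σ²_SCA = 5, σ²_ε = 50, and analyses it:

```
simulated 840 roots over 28 crosses
MS_GCA =   130.31   MS_SCA =   8.87   df = 7, 20
V_GCA  =    20.24   (simulated 25.0)
V_SCA  =     6.84   (simulated  5.0)
V_eps  =    49.97   per-root basis (simulated 50.0)
V_A    =    40.48   V_D =   6.84   (F = 1)
H²     =     0.98   h² =   0.84   Baker's ratio = 0.97
```

The estimated components recover the simulated ones up to the sampling
noise of a single 28-cross trial (the acceptance suite averages 200 such
trials); H² and h² are the fractions of phenotypic variance on a
plot-mean basis attributable to all genetic effects and to additive
effects only. The other examples show single-root measurement against
ground truth (`measure_synthetic_root.py`), the root-fill shape space
(`root_fill_pca.py`), and photograph segmentation (`segment_photo.py`).
A thin CLI wraps the same library calls:

```sh
taproot simulate --out masks/ --n-roots 20 --diallel
taproot all --input-dir masks/ --out results/ --diallel-csv masks/diallel_phenotypes.csv -p 8
```

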