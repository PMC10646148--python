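# neuromorph

Semi-automated morphometry of motor-neuron neurite networks in two-channel
fluorescence microscopy, with a synthetic acquisition generator that carries
exact ground truth for every measurement stage.

## The problem

Cultured iPSC-derived spinal motor neurons form dense neurite networks whose
architecture changes under genetic perturbation. A standard readout compares
wild-type and knockout lines by imaging fields stained with a nuclear dye
(DAPI) and the somatodendritic marker Map2, segmenting the neurite network,
skeletonizing it, and counting — per acquisition — somata, branches,
junctions, end-points, total branch length and average branch length, then
testing group differences by one-way ANOVA with post-hoc comparisons.

`neuromorph` reimplements that Fiji/ImageJ-style workflow as a tested Python
library:

1. **Nuclei/soma mask** (DAPI): Huang minimum-fuzziness threshold → removal
   of components with equivalent-circle radius < 20 px → Euclidean dilation
   by 5 px (the cytoplasmic rim of a mature motor neuron).
2. **Neurite mask** (Map2, duplicated): a *high-intensity mask*
   (0.1%-saturation contrast stretch → σ = 2 µm Gaussian blur →
   moment-preserving threshold) catching somata, hillocks and bright cores,
   and a *LoG mask* (contrast stretch → inverted Laplacian-of-Gaussian →
   moment-preserving threshold) catching thin faint segments; the final mask
   is `(high ∪ LoG) \ soma`.
3. **Skeleton morphometry**: topology-preserving thinning; skeleton pixels
   classified by 8-neighbor count (endpoint ≤ 1, slab = 2, junction ≥ 3);
   adjacent junction pixels merged into one junction; branches are maximal
   slab paths between terminals with length Σ(orthogonal steps · s +
   diagonal steps · √2·s) at pixel size s = 0.207 µm.
4. **Per-cell scoring**: nucleus-derived regions, per-cell marker
   intensities on maximum-intensity projections, and CHAT⁺/ISLET1⁺
   double-positive fractions from automatic thresholds.
5. **Statistics**: one-way ANOVA + Tukey HSD (or Bonferroni), boxplot
   summaries (median, quartiles, Tukey-fence outliers), two-tailed Student
   t tests, star convention `*`…`****` at 0.05…0.0001.

The Huang and Tsai (moments) histogram thresholds, the skeleton-graph
analysis and the growth-model generator are implemented in this package;
standard filters, labeling, thinning primitives and statistics come from
scipy/scikit-image/tifffile/pandas.

Because the original confocal images are not public, the package ships a
**synthetic generator**: 212.3 µm fields at 0.207 µm/px with non-overlapping
nuclei and neurite trees grown by stochastic segment elongation (exponential
segment lengths above a minimum spacing, angular jitter, bifurcation with
probability `branching_prob`, stop at field edge or depth cap), rendered
with width-dependent intensity falloff, somatic Map2 glow, additive
background and Poisson + Gaussian noise. Every acquisition comes with the
true neurite graph and the morphometry computed analytically from it, so
recovery and phenotype-direction claims are testable.

## Worked example

```python
import dataclasses
import pandas as pd
from neuromorph import (GeneratorParams, generate_group, measure_acquisition,
                        anova_multicompare)

wt = GeneratorParams()                                    # wild-type defaults
ko = dataclasses.replace(wt, branching_prob=wt.branching_prob / 2)
items = generate_group(wt, ko, n_images_per_group=10, n_replicates=3,
                       master_seed=7)                     # 30 images/group
df = pd.DataFrame([measure_acquisition(i.acquisition).as_dict() for i in items])
print(df.groupby("group")[["n_branches", "n_junctions",
                           "avg_branch_length_um"]].mean().round(2))
cmp_ = anova_multicompare(df, "n_branches")
print(f"branches: F = {cmp_.f_stat:.1f}, p = {cmp_.p_value:.2e}")
```

Output (master seed 7):

```
       n_branches  n_junctions  avg_branch_length_um
group
KO          194.1        44.23                 11.06
WT          304.6        76.03                  8.94
branches: F = 72.2, p = 8.97e-12
```

Halving the branching probability lowers branch and junction counts and
*raises* the average branch length — the sparser network has fewer
intersections, so the surviving slab segments are longer. Soma counts stay
identical by design (equal plating density across groups).

The same pipeline is scriptable from the shell:

```bash
neuromorph simulate --out data/ --seed 7 --n-images 10 --n-replicates 3
neuromorph measure --in data/ --out metrics.csv
neuromorph report --metrics metrics.csv --out report.json --plots plots/
```

## Limitations

Junction counts sit at the resolution limit of the published mask scale: a
2 µm filter produces a ~4 µm-wide mask, so branch points closer than the
mask width merge and short daughter branches can be swallowed entirely. See
`docs/methods.md` for the quantitative analysis and all modeling choices.
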