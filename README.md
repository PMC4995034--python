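# wingmorph

Landmark-based wing geometric morphometrics for insect species
identification.

Mosquitoes of the genera *Aedes*, *Anopheles* and *Culex* transmit dengue,
malaria, filariasis and West Nile virus, and reliable species identification
is a prerequisite for understanding transmission — yet taxonomic keys fail on
damaged specimens and on cryptic or sibling species. Wing venation geometry
is a cheap, robust alternative: the coordinates of homologous vein
intersections (landmarks), once translation, scale and rotation are removed,
carry enough shape information to separate genera, subgenera and species.

`wingmorph` implements the complete identification pipeline for 2-D wing
landmark data, plus a synthetic-data generator that emulates a 12-species,
3-genus study design (18 landmarks per wing) so every stage can be exercised
and calibrated without access to original wing photographs.

## Methods at a glance

- **Generalized Procrustes analysis (GPA).** Configurations
  $X_i \in \mathbb{R}^{k \times 2}$ are centred, scaled to unit centroid size
  $CS = \sqrt{\sum_j \lVert x_j - \bar{x} \rVert^2}$, and iteratively rotated
  to the consensus $\bar{X}$; shapes are analysed as tangent-space coordinates
  at the consensus.
- **Allometry.** Multivariate regression of tangent coordinates on
  $\log CS$; the statistic is the percent of total shape variance predicted,
  tested by permutation of the size vector (10,000 randomizations by default).
- **Canonical variate analysis (CVA) and Mahalanobis distance.** After a
  principal-component reduction (the pooled within-group covariance of
  $2k - 4$ tangent dimensions is otherwise singular at realistic sample
  sizes), canonical axes solve $B v = \lambda W v$ with Mahalanobis scaling
  ($v^\top W v = 1$), and group separation is measured by
  $D_{ij} = \sqrt{(\mu_i - \mu_j)^\top W^{-1} (\mu_i - \mu_j)}$.
- **Cross-validated reclassification.** Strict leave-one-out: each specimen
  is assigned to the nearer group mean by Mahalanobis distance, with the
  reduction, means and pooled covariance re-estimated per fold; results are
  reported as the asymmetric pairwise percent-correct table.
- **Thin-plate splines.** Deformation grids and wireframes with kernel
  $U(r) = r^2 \log r^2$, exact at landmarks, with bending energy zero for
  affine shape change; shapes at canonical-axis extremes are obtained by
  regressing tangent coordinates on CV scores.
- **Neighbor-joining tree.** Saitou–Nei agglomeration on the species
  Mahalanobis matrix, with bootstrap supports from resampling specimens
  within taxa (1,000 replicates by default) and optional outgroup rooting;
  Newick-serializable.

## Worked example

```python
import wingmorph as wm

# simulate the 12-species study design and superimpose
dataset = wm.generate(wm.make_default_spec(seed=42))
proc = wm.generalized_procrustes(dataset)

# allometry: percent of shape variance predicted by log centroid size
allo = wm.allometry_regression(proc, n_permutations=999, seed=0)
print(f"allometry: {allo.percent_predicted:.2f}% of shape variance, "
      f"p = {allo.p_value:.4g}")

# genus-level ordination and cross-validated reclassification
genus_cva = wm.cva(proc, "genus")
print(genus_cva.mahalanobis.round(2))
table = wm.pairwise_table(proc, "genus")
print(table.percent_correct.round(1))
print(f"mean accuracy: {table.mean_rate:.1f}%")
```

prints

```
allometry: 7.08% of shape variance, p = 0.001
           Aedes  Anopheles  Culex
Aedes       0.00       9.13   7.56
Anopheles   9.13       0.00   7.66
Culex       7.56       7.66   0.00
           Aedes  Anopheles  Culex
Aedes        NaN      100.0  100.0
Anopheles  100.0        NaN  100.0
Culex      100.0      100.0    NaN
mean accuracy: 100.0%
```

The allometric fraction is the regression estimate for this one simulated
dataset (the generator injects 5.91% in expectation; single-dataset estimates
scatter around that). The Mahalanobis matrix says the three genus mean shapes
sit 7–9 pooled within-group standard deviations apart, which is why the
pairwise leave-one-out reclassification between genera is perfect.

## Command line

```
wingmorph simulate --preset mosquito12 --seed 1 --out data.tps --classifier labels.csv
wingmorph run --preset mosquito12 --seed 1 --out results/
wingmorph run --tps data.tps --classifier labels.csv --out results/
wingmorph allometry|cva|classify|subsets|tree --help
```

`wingmorph run` writes the consensus shape, centroid sizes, the allometry
report, CVA scores/plots and reclassification tables at genus, subgenus and
species level, per-genus species morphospaces, a landmark-subset evaluation
(5-, 7- and 9-landmark sets), the bootstrapped NJ tree, and a
`manifest.json` with the seed, a configuration hash, and SHA-256 checksums of
every output; re-running the same configuration reproduces every file
bit-exactly.

Data are read from TPS-dialect landmark files (`LM=`, coordinate pairs,
`ID=`, `IMAGE=`, `SCALE=`) with a CSV classifier table
(`specimen_id,genus,subgenus,species,site`).

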