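# chromascope

Multiscale analysis of Hi-C contact maps: insulation and TAD boundaries,
A/B compartments, chromatin-loop hierarchies, and in-silico perturbation
screening of chromatin tracks — with a synthetic map generator that plants
known structure so every step can be validated against ground truth.

## Who this is for

Chromatin-structure researchers who need the quantitative machinery around a
contact-map predictor or an experimental Hi-C dataset: normalizing raw counts,
scoring domain boundaries and compartmentalization, organizing loop calls into
nested hierarchies, and asking "what happens to the 3-D map if I silence this
1-kb of accessibility signal?" — without a GPU or a trained neural network.
A deterministic mechanistic surrogate stands in for a learned sequence-to-map
predictor, so the perturbation/screening workflow is fully exercisable on a
laptop; any external predictor can be plugged in behind the same contract.

## The quantities at the core

**Insulation ratio.** For bin *i* and a window of *w* bins on each side,
with *L* and *R* the mean intensities of the two intra-side square blocks and
*M* the mean of the cross block,

    INSUL(i) = (L + R + Const) / (M + Const)

where *Const* is the average intensity of the map (mean over observed, i.e.
nonzero unmasked, contacts). A uniform map gives INSUL = 1.5 everywhere; a
perfect boundary between two uniform blocks gives INSUL = 3. TAD boundaries
are called separately, as delta-vector minima of the standard sliding-diamond
insulation track.

**Compartmentalization order parameter.** Given per-bin A/B labels and a
fold-over-expected map, with AA, AB, BA, BB the mean intensities over
off-diagonal bin pairs in each label quadrant,

    COMP = (AA + BB) / (AB + BA),     COMP_rescaled = (COMP − 1) / (COMP + 1)

so COMP_rescaled = 1 means contacts occur only within compartments and
COMP_rescaled = −1 only across. Labels come from spectral clustering of the
contact graph (normalized-Laplacian eigenvectors, 2-way clustering, then a
1-D linear-discriminant axis as the signed score).

**Loop hierarchy and valency.** Loop α is a sub-loop of loop β iff
β_l ≤ α_l < α_u ≤ β_u (identical pairs excluded). Main-loops are enclosed by
no other loop; the valency of a main-loop is the number of loops nested
within it at any depth.

**Impact score.** For a perturbation of a 1-kb fragment, the mean absolute
difference between the predicted log-fold maps before and after, over a
scale-sized window centered on the fragment. The top decile of fragments per
scale forms the HIS (high-impact-score) subset.

## Worked example

Generate a synthetic 6.4-Mb region (25-kb bins, 8 TADs, pairwise-grouped A/B
compartment blocks, nested loops in the outermost TADs), sample Poisson
counts, and run the analysis stack:

```python
import numpy as np
from chromascope import synthetic, matrixio, insulation, compartments, loops

truth = synthetic.make_truth(seed=1)
lf = synthetic.render_logfold(truth)
counts = synthetic.sample_counts(lf, decay_exponent=1.0, depth=500, seed=1)

balanced = matrixio.filter_low_coverage_bins(matrixio.ice_balance(counts))
oe = matrixio.log_fold_oe(balanced)

bounds = insulation.tad_boundaries(oe, window=400_000)
print("planted boundaries:", truth.boundaries.tolist())
print("called boundaries: ", bounds.positions.tolist())

tracks = synthetic.make_tracks(truth)
ref = tracks["atac"].bin_means(truth.config.resolution)
labels = compartments.compartment_labels(balanced, reference=ref)
print(f"compartment label accuracy: {np.mean(labels.label == truth.labels):.3f}")
score = compartments.comp_score(oe, labels)
print(f"COMP = {score.comp:.3f}, COMP_rescaled = {score.comp_rescaled:.3f}")

h = loops.loop_hierarchy(truth.loops)
print(loops.loop_stats(h, truth.config.n_bins * truth.config.resolution))
```

Output:

```
planted boundaries: [32, 64, 97, 130, 158, 190, 226]
called boundaries:  [32, 63, 97, 129, 158, 190, 225]
compartment label accuracy: 1.000
COMP = 2.133, COMP_rescaled = 0.362
{'count_per_mb': 0.625, 'mean_main_size': 600000.0, 'mean_valency': 1.0,
 'mean_size_per_valency': 600000.0}
```

Every planted TAD boundary is recovered within one bin from the noisy counts,
the compartment call matches the planted labels exactly, and COMP_rescaled of
0.36 reflects the moderate planted checkerboard contrast (0.6 log-fold
units). The loop summary reports 4 loops over 6.4 Mb, two main loops of
600 kb each carrying one sub-loop apiece.

The same steps are available from the shell:

```
chromascope simulate --seed 1 --depth 500 --out sim/
chromascope balance sim/matrix.triplet.txt --bins sim/bins.tsv --out sim/balanced.txt
chromascope tads sim/balanced.txt --bins sim/bins.tsv --window 400000 --out sim/tads.bed
chromascope screen --atac sim/atac.bedGraph --ctcf sim/ctcf.bedGraph \
    --chrom chr1 --start 0 --end 304000 --scale 256000 --out sim/screen.tsv
```

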