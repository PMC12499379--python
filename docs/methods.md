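# Methods

This note records the models and procedures implemented in chromascope, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Contact-map model and normalization

Maps are dense symmetric per-chromosome matrices over a cool-convention bin
table (0-based half-open coordinates; bin index = floor(start/resolution)).
Invalid bins carry NaN across their whole row and column; NaN is excluded
from every mean and is never conflated with an observed zero. Trans
(inter-chromosomal) contacts are out of scope.

**ICE balancing** equalizes the marginals of valid rows by alternating
division by the row/column sums, stopping when the coefficient of variation
of the valid-row sums falls below `tol` (default 1e-5, `max_iter` 200 —
standard iterative-correction settings). Bins with an all-zero marginal
cannot be balanced and are masked before iterating. The multiplicative bias
vector is retained. After balancing, bins with fewer than 10 nonzero row
entries are masked by `filter_low_coverage_bins` (the conventional
low-coverage cut).

**Distance-decay expected and log-fold.** The expected value at separation
*d* bins is the mean over valid pairs on that diagonal (NaN where no valid
pair exists — never zero). The observed/expected transform is
`log((m + pc) / (expected + pc))` with pseudocount `pc` defaulting to 0:
balanced intensities at the depths we model are bounded away from zero, and
a pseudocount would bias the closed-form identities (exp(lf)·expected
recovers the input exactly at pc = 0). It is configurable for sparse inputs.

**Pooling** is 2-D block averaging; a trailing partial block is averaged
over its actual members. An output bin is masked only when every source bin
was masked. Pooling a `LogFoldMatrix` also pools its expected vector by
simple averaging — adequate for the factor-2..4 coarsenings used here, since
the expected is recomputed from scratch wherever precision matters.

## Insulation: two scores on purpose

Two distinct insulation notions coexist:

* the **sliding-diamond score** (mean contact over the w×w cross block at
  each bin) is the boundary *detector*: its delta vector (mean over
  `delta_bins` upstream minus downstream, default 3) crosses zero downward
  at local minima, which are called as TAD boundaries. Boundary scores are
  the zero-crossing depth. At matrix edges the score is undefined rather
  than computed on shrunken windows.
* the **INSUL ratio** `(L + R + Const)/(M + Const)` is the boundary
  *strength* readout, evaluated at called boundaries. L and R are the mean
  intensities of the two intra-side squares `[i-w,i)²` and `(i,i+w]²`, M the
  mean of the cross block — this geometry is the one under which stronger
  boundaries score higher.

**The constant.** `Const` is "the average intensity of the map", read as the
mean over *observed* (nonzero, unmasked) contacts. In a sparse contact map a
zero entry is an unobserved pair, not a measured absence, so the observed
mean is the natural intensity scale. This reading also preserves both
closed-form identities: INSUL = 1.5 on uniform maps and INSUL = 3 at a
perfect two-block boundary (an all-entry mean would give 5 for the latter).
INSUL is invariant under global rescaling of the map, since L, R, M and
Const all scale together.

**Differential insulation.** The perturbation response of a fragment is the
perturbed-minus-original insulation curve; its peak is the extremum of the
absolute difference near the perturbed site, and the impact width counts the
contiguous bins around the peak that share the peak's sign, peak included
(the two arms are also recorded separately — "maximum bin number in both
directions" admits either a sum or a per-arm reading; the sum is reported).
Identical profiles return a null-peak record rather than an error.

## Compartments

The contact matrix is treated as a graph adjacency (log-fold inputs are
exponentiated to fold space first; negative affinities are clipped to 0).
Each diagonal of the affinity is divided by its mean before anything else
(`detrend_distance=True`): this observed/expected step is standard in
compartment analysis, and without it residual distance decay or
domain-scale banding dominates the graph cut and the spectral call degrades
to a contiguous split. The symmetric normalized Laplacian is
eigendecomposed; the 50 leading eigenvectors (clipped to the valid-bin
count) are weighted by (1 − λ)² — a diffusion-map-style emphasis of smooth
structure over high-frequency noise directions, without which a flat-weighted
k-means in 50 dimensions is noise-dominated — and clustered into two groups
by k-means (fixed seed, 10 restarts). A one-component linear-discriminant
axis fit on the cluster labels yields the signed per-bin score; label A is
score > 0. The sign is oriented so A has the higher mean of a
caller-supplied reference track (accessibility or CpG density); without a
reference the orientation is arbitrary and flagged (`oriented=False`).

**COMP.** Quadrant means AA, AB, BA, BB are taken over unmasked off-diagonal
pairs in fold space ("contact probabilities" averaged as fold-over-expected;
a `space="linear"` mode averages the values as given, which matters for
limit cases with exact zeros where the log is undefined). COMP =
(AA+BB)/(AB+BA), rescaled to (COMP−1)/(COMP+1) ∈ [−1, 1]; the
zero-denominator limit with positive intra-compartment contact is defined as
+1. Swapping all labels leaves COMP unchanged. Sub-compartment (≥3 state)
calling and trans-chromosomal analysis are out of scope.

## Loops

Nesting follows the coordinate rule β_l ≤ α_l < α_u ≤ β_u with identical
pairs excluded; duplicates are removed (with a warning) before the hierarchy
is built, since two identical loops would otherwise nest in each other.
A loop's parent is its *smallest enclosing* loop, ties broken by size, then
lower coordinate, then input order — enclosers need not form a chain when
intervals partially overlap. Valency counts every loop nested in a main-loop
at any depth by the coordinate rule (not only direct children). With
crossing main-loops a nested loop can be counted under more than one main,
so the partition identity Σ_mains (1 + valency) = n holds exactly only for
laminar (nested-or-disjoint) families; single-resolution loop sets are
near-laminar in practice.

Anchor categories (P–P, E–P, E–E, other) come from overlap of a ±10-kb
anchor window (loop calling is typically done at 10-kb resolution) with
promoter/enhancer annotations; an anchor hitting both counts as promoter.
`mean_size_per_valency` is the ratio of the mean main-loop size to the mean
valency over main-loops, valency-0 mains included in both means (a per-loop
mean of size/valency is undefined at valency 0).

**Naive caller.** A deliberately simple donut-enrichment caller for
synthetic maps: candidate pixels are strict local maxima of the fold-space
map at ≥3 bins separation, scored by a one-sided Poisson test of the pixel
against the surrounding ring mean, both scaled by a nominal depth of 100
pseudo-reads, with a minimum fold enrichment of 1.5 over the ring. It is
plumbing for planted-bump maps and threshold-sweep curves, not a substitute
for callers trained on experimental Hi-C.

## Perturbation engine and the surrogate predictor

Track operators: region silencing (zeroing), enhancer activation (pointwise
max with a donor track, or a fold factor — 1.1 being the conventional mild
global activation), Gaussian CTCF peak addition (apex 1000, support = motif
length + 30 bp each side, σ = support/6, combined with the original by
pointwise max), global fold scaling, and 16-bp segment-shuffle sequence
permutation (seeded; trailing remainder fixed).

The **surrogate predictor** maps (ATAC, CTCF) tracks to a log-fold map
deterministically, composing three mechanistic responses on a window of *n*
bins:

    logM[i,j] = κ_comp · s_i s_j
              + Σ_pairs κ_loop · exp(−((i−p)² + (j−q)²) / 2σ_loop²)
              − κ_ins · min(n_bound(i,j), cap)

* *s* is the bounded z-score (tanh) of the ATAC per-bin means smoothed with
  a 100-kb Gaussian half-width — the compartment field.
* CTCF sites are bins whose per-bin CTCF maximum exceeds θ_c = 2. Sites
  that are *accessible* (per-bin ATAC maximum above θ_a = 2, a focal-peak
  level above plateau accessibility) and *partnered* within d_max = 1 Mb
  are loop anchors; every anchor pair contributes a Gaussian bump
  (σ_loop = 2 bins, apex κ_loop = 1.5).
* All remaining CTCF sites insulate: each boundary strictly between i and j
  subtracts κ_ins = 0.3, capped at 3 crossings. Silencing the ATAC under an
  anchor therefore removes its loop bumps *and* converts the site into an
  insulating boundary — the behavior of an extrusion barrier that lost its
  partner. κ_comp = 0.4; all parameters sit in `SurrogateConfig`.

The surrogate is a mechanistic model in its own right — compartment
attraction, CTCF-anchored loops, boundary insulation — chosen so that maps
built from structure-consistent tracks reproduce that structure under the
analysis stack. It is deterministic (bit-identical outputs for identical
inputs) and local (edits outside the prediction window change nothing).

**Screening.** The span is cut into 1-kb fragments; for each fragment and
scale, a scale-sized window (64 bins by default, clipped and shifted inside
the span at chromosome ends) is centered on the fragment, the fragment's
ATAC signal is silenced, and the impact score is the mean absolute
prediction difference over the window. The HIS subset is the top decile per
scale; ties break by impact rank then genomic coordinate, so the result is
deterministic even for all-zero tracks. Two caveats discovered during
validation: (i) the window-level z-score makes the compartment term
sensitive to any in-window edit, so at large scales plateau edits can score
comparably to anchor edits — anchor-versus-plateau ranking is a
smallest-scale (256-kb) property; (ii) windows clipped at span edges
overweight edge samples through the smoothing boundary condition, so
span-edge fragments can rank high artificially — screens should extend the
span beyond the region of interest where possible.

## Synthetic generator

`make_truth(config, seed)` plants, reproducibly: TAD boundaries at jittered
equal spacings; compartment labels alternating over runs of
`tads_per_block` TADs (so compartment switches coincide with TAD boundaries,
as in real genomes — and necessarily so here, since a compartment edge
inside a TAD would register as an insulation minimum); and nested loops in
the two outermost TADs (maximally separated so anchor pairs never bridge
TADs within d_max), each TAD holding one main loop with `loop_valencies[k]`
sub-loops at 5-bin nesting offsets. Defaults: 256 bins × 25 kb (6.4 Mb),
8 TADs (~0.8 Mb), 2 TADs per compartment block (~1.6 Mb blocks) — sizes in
the realistic range for mammalian chromatin at this resolution.

`render_logfold` composes the structure on a zero log-fold baseline:
checkerboard κ·s_i s_j (0.6), TAD block elevation (0.4), Gaussian loop bumps
(1.5, σ = 2 bins). The power-law distance decay lives in the expected
vector, not the log-fold layer, matching the fold-over-background map
representation. `sample_counts` draws independent Poisson counts per
upper-triangle pair with mean depth · d^(−γ) · exp(lf) (γ = 1, a typical
intra-chromosomal decay; d floored at 1 bin) and mirrors them.
`make_tracks` emits tracks consistent with the truth: an ATAC plateau of 1.5
over A bins (0.2 over B) with single 1-kb peaks of 3.0 at anchor-bin
centers, and CTCF peaks of 3.0 at boundary and anchor bins (track step
1 kb). Silencing one 1-kb piece thus deletes exactly one anchor.

**What passing tests show — and don't.** The generator produces clean,
block-structured maps with Poisson noise only: no coverage bias beyond what
ICE is asked to remove, no unmappable regions, no decay-exponent variation,
no loop anchors without CTCF, no compartment transitions away from TAD
boundaries. Recovery results (boundaries within ±1 bin, ≥90% label accuracy,
exact main-loop counts across seeds) validate the *implementations* against
planted truth under these idealized conditions; they are not performance
claims about experimental Hi-C.

## Problem sizes and numerical choices

Validation runs use 96–256-bin maps (2.4–6.4 Mb at 25 kb), screens of 100–
300 1-kb fragments at the 256-kb scale, and 10–20 generator seeds —
comfortable desk-scale sizes for a dense-matrix implementation. TAD calling
in the pipeline tests uses a 400-kb window, about half the planted 0.8-Mb
TAD size, the same proportion as the conventional 1-Mb window for ~Mb real
TADs. Degenerate inputs raise typed errors rather than returning silent
values: all-zero maps (balancing, insulation), constant affinities
(compartments), single-class label sets (COMP, AUROC). Eigendecomposition
uses LAPACK `eigh` on the dense symmetric Laplacian; k-means is seeded;
AUROC uses the rank-sum identity and is exact under ties.

## Known limitations

Dense matrices bound practical map sizes to a few thousand bins per
chromosome; no cool/HDF5 container support (text triplet/dense formats
only); per-chromosome analysis only; the naive loop caller is not meant for
experimental data; the surrogate's window-global z-score couples distant
in-window edits (see screening caveats above); forest/prairie and CpG-class
partitions are consumed as annotations, never derived.
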