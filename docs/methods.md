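# Methods

## Problem and model

`sscparc` parcellates a small brain structure (prototypically the amygdala)
into k functionally homogeneous, spatially coherent subregions from
resting-state fMRI voxel time series, guided by a coarse anatomical atlas.
The ROI's N voxels form a fully connected graph with edge weights

    f_uv = r_uv + 1 ∈ [0, 2],

where r_uv is the Pearson correlation of the two voxels' band-passed time
courses. A partition {g_c} of the voxels into k clusters is scored by

    J = Σ_c [ Σ_{u,v∈g_c, u≠v} f_uv
              + λ·α     · Σ_{u,v∈g_c} P_uv
              + λ·(1−α) · Σ_{u,v∈g_c} e_uv ] / Σ_{u∈g_c, v∈V} f_uv

and maximized. The first (data) term is the normalized association: with
λ = 0 the method reduces to the unsupervised normalized-cut (NCUT)
baseline. P restricts f to pairs of voxels inside the same *prior region*
(rewarding clusters that keep each prior together), and e restricts f to
spatially adjacent pairs (26-connectivity by default; configurable 6/18/26
— the notion of "spatially nearest neighbors" is a convention, not a
physical fact). All three numerator matrices have zero diagonals; every
denominator uses f only.

Defaults λ = 2, α = 0.5 weight prior and spatial terms equally at twice
half the data term's scale; k = 3 matches the three cytoarchitectonic
subregions (centromedial, laterobasal, superficial) of the amygdala.

## Prior extraction

Anatomical atlases are only coarsely aligned with function, so clusters are
anchored not to whole atlas subregions but to one small, functionally
homogeneous region per subregion:

1. **ReHo.** Regional homogeneity is Kendall's coefficient of concordance W
   of each voxel's time course with its in-mask neighborhood (27 voxels by
   default; mid-ranks for ties, no tie correction; K shrinks at mask edges
   rather than padding, because out-of-structure signal would contaminate
   homogeneity). ReHo must be computed on unsmoothed data.
2. **Watershed.** Each atlas subregion is watershed-segmented on −ReHo with
   markers at ReHo local maxima after h-maxima suppression (h = 0.05
   default; larger h merges noise peaks). Basins under `min_size = 5`
   voxels are dropped; if all basins are dropped the largest is retained.
3. **MinMaxCut selection.** One basin per subregion is chosen to minimize
   Mcut = Σ_i (between-sum of p_i to the other priors)/(within-sum of p_i),
   sums over ordered pairs u ≠ v. `exhaustive` enumerates all one-per-label
   combinations (capped at 10^5; the cap is never near in practice — basin
   counts per subregion are single-digit); `greedy` seeds with the densest
   basin per label and hill-climbs. Greedy's density seeding favors very
   small basins and occasionally picks a basin on the wrong side of a
   misaligned atlas boundary; exhaustive is the default.

## Solver

The objective is optimized by weighted kernel k-means using the standard
graph-cut equivalence: weights w_u = d_u = Σ_v f_uv, combined affinity
W = f + λαP + λ(1−α)e, kernel

    K = σ·diag(1/w) + diag(1/w)·W·diag(1/w),

with σ the smallest diagonal shift making K positive semidefinite
(σ = max(0, −λ_min(D⁻¹WD⁻¹))·max(w) + ε). The shift guarantees each batch
iteration does not decrease J, but it also makes the assignment step very
conservative — with strongly indefinite affinities the batch phase can stay
at its initialization. The solver therefore follows the batch phase with
**incremental refinement**: single-voxel moves that strictly increase J,
evaluated in O(k) per candidate move from maintained cluster sums, applied
until a 1-move local maximum. Only improving moves are accepted, so the
full objective trace remains monotone. Empty clusters are rescued by
reassigning the voxel with the worst within-cluster affinity; ties in the
assignment step break toward the current label for stability.

Initialization: prior voxels take their prior's label; remaining voxels
join the prior of maximal mean similarity; `n_restarts − 1` further starts
perturb 20% of the non-prior voxels. NCUT uses k-means++-style seeding on
the similarity graph. One root seed drives all restarts; results are
bit-stable for a fixed seed.

Because J is invariant under label permutations, cluster identities are
anchored after solving: each cluster takes the label of the prior region it
overlaps most (optimal one-to-one assignment). For cohort-level
consistency analyses, both SSC and NCUT labelings are additionally matched
to the atlas by the same maximum-overlap rule, so entropy compares
partition geometry rather than naming conventions.

On 10-voxel instances the multi-restart solver attains the exhaustive
maximum over all partitions into 3 nonempty blocks (verified over random
instances in the test suite).

## Evaluation

- **Dice** 2|X∩Y|/(|X|+|Y|) between voxel sets.
- **Modified silhouette** SI = mean_c (a_c − b_c)/max(a_c, b_c) with
  a_c the mean within-cluster similarity over ordered pairs and b_c the
  mean cluster-to-rest similarity; singleton clusters and the
  all-one-cluster case are rejected (undefined).
- **Volumes** = voxel count × voxel volume.
- **Probability maps** use the full cohort size as denominator, so per-voxel
  frequencies sum to the fraction of subjects labeling that voxel.
- **Maximum probability map**: a voxel is included iff its cumulative label
  frequency ≥ 0.60 (⇔ "at least 12 of 20 subjects") or any single label
  ≥ 0.50; it takes the arg-max label; exact ties go to the label with the
  highest mean frequency over the 3×3×3 neighborhood, residual ties to the
  lowest label (logged).
- **Cross-subject entropy** H(u) = −Σ_k Pr(u=k)·log Pr(u=k), natural log by
  default (configurable to base 2), with Pr renormalized over the subjects
  that assign any label at u; unlabeled voxels are skipped. Lower mean H =
  higher consistency.
- **FC maps**: per-voxel Pearson correlation with the seed-mean time course,
  Fisher z = atanh(r) with |r| clipped to 1 − 1e−7; voxelwise one-sample or
  paired t-maps, explicitly uncorrected (cluster-level family-wise-error
  correction needs smoothness/permutation machinery and is out of scope).

## Synthetic data

The generator produces what the method assumes and nothing more: an
ellipsoidal ROI (≥ 200 voxels) partitioned into k contiguous subregions
(discrete Voronoi cells of k farthest-point seeds, connectivity enforced),
each subregion sharing a latent band-limited Gaussian time course. Voxel
series are latent × snr + unit white noise, band-pass filtered (zero-phase
order-4 Butterworth, 0.01–0.08 Hz at TR = 3 s, T = 190 — a typical
resting-state acquisition). Series are simulated with a 64-sample burn-in
margin and trimmed, so filter edge transients never reach the delivered
data; ≥ 90% of every voxel's power lies in the passband.

Cohorts share one template truth; each subject's subregion seeds are
jittered by `boundary_jitter_vox` (inter-subject variability). All subjects
share a single prior atlas derived once from the template truth — seeds
shifted by `prior_mismatch_vox` plus random reassignment of a fraction
(default 0.3) of boundary voxels — mirroring a study design in which one
fixed atlas is applied to every participant. A standalone subject derives
its own prior the same way from its own truth.

What the generator does **not** emulate: hemodynamics, motion and
physiological artifacts, spatially correlated noise (optional Gaussian
smoothing of the noise field is available but off by default), partial
correlation between the subregions' latents, and EPI distortion. Passing
tests therefore show algorithmic correctness and the direction of effects
under idealized conditions, not performance on real acquisitions.

### A note on the baseline comparison regime

With independent latents and snr = 1, the within-subregion correlation
after filtering is ≈ 0.7: the functional signal alone identifies each
subject's true partition almost perfectly, so the unsupervised baseline
already sits at the consistency floor set by the true boundary jitter, and
the prior's consistency benefit is marginal (it can only re-appear as the
atlas pull biases all subjects toward the same template). The benefit
becomes large and systematic when the data term is ambiguous: at snr = 0.25
the prior-guided method is markedly more consistent across subjects and
closer to the atlas than the baseline (verified in the test suite). Real
resting-state data, with within-region correlations of ~0.1–0.3, lives in
that ambiguous regime.

## Numerical choices

- Degenerate inputs: zero-variance time series get correlation 0 (flagged);
  isolated voxels get ReHo 0; empty ROIs, empty clusters, singleton SI
  clusters, sub-2-voxel prior regions are errors.
- Mcut/objective sums use ordered pairs; diagonals are zero everywhere.
- NaNs are rejected on load by default (`allow_nan` zero-fills, logged).
- Dense N×N matrices throughout: N ≈ 300–1500 voxels per structure, so
  O(N²) memory and O(N²k) per solver sweep are trivial at this scale.
- Simulation sizes in tests: 12³ grids (~550-voxel ROI), cohorts of 12–20,
  5–20 seeds per property — sizes at which every property is stable while
  the full suite stays fast.

## Known limitations

- The identity anchoring assumes each selected prior truly lies in "its"
  functional subregion; a basin inside a grossly misaligned atlas strip can
  permute cluster identities for that subject (the cohort-level overlap
  matching mitigates, and exhaustive Mcut selection reduces, this failure).
- The solver finds 1-move local maxima; global optimality is verified only
  at small N.
- The NCUT baseline here is the same kernel k-means machinery at λ = 0 with
  strong restarts, which is a *stronger* baseline than spectral-relaxation
  implementations; comparisons against it are conservative.
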