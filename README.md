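# sscparc

Semi-supervised spectral clustering (SSC) parcellation of small brain
structures — prototypically the human amygdala — into k functionally
homogeneous, spatially coherent subregions from resting-state fMRI voxel
time series, guided by a coarse anatomical atlas.

Unsupervised connectivity-based parcellation of a structure as small as the
amygdala (~2 cm³, a few hundred voxels) is unstable: the functional signal
rarely determines boundaries or subregion identity on its own. `sscparc`
anchors the clustering with *prior regions* — one small, functionally
homogeneous region per atlas subregion — and optimizes

    J({g_c}) = Σ_c [ Σ_{u,v∈g_c, u≠v} f_uv
                     + λ·α     · Σ_{u,v∈g_c} P_uv
                     + λ·(1−α) · Σ_{u,v∈g_c} e_uv ] / Σ_{u∈g_c, v∈V} f_uv

over partitions {g_c} of the ROI voxels, where f_uv = r_uv + 1 is the
correlation-based similarity, P keeps f within prior regions, e keeps f
between spatial neighbors, and λ = 2, α = 0.5 by default. The objective is
maximized by weighted kernel k-means (graph-cut equivalence with f-degree
weights) plus incremental single-voxel refinement. Setting λ = 0 gives the
unsupervised normalized-cut (NCUT) baseline.

The package also provides:

- prior extraction: regional homogeneity (Kendall's W), marker-based
  watershed per atlas subregion, MinMaxCut selection of the prior triple;
- evaluation: Dice overlap, modified silhouette width, subregion volumes,
  cohort probability maps, maximum probability maps (60%/50% inclusion
  rules with 3×3×3 tie-break), cross-subject label entropy;
- seed-based functional-connectivity maps with Fisher r-to-z and voxelwise
  (uncorrected) group t-maps;
- a synthetic-data generator (single subjects and cohorts with planted
  contiguous subregions, band-limited signals, a deliberately misaligned
  prior atlas, and jittered inter-subject boundaries) so the entire
  pipeline runs and is tested without external data.

## Worked example

Simulate a subject, parcellate it with and without the atlas prior, and
evaluate:

```sh
sscparc simulate --out sim --subjects 1 --seed 3 --snr 2.0
sscparc parcellate --fmri sim/sub-00_fmri.nii.gz --mask sim/sub-00_mask.nii.gz \
    --atlas sim/sub-00_prior.nii.gz --method ssc --seed 17 \
    --out sim/sub-00_ssc.nii.gz --report sim/report.json
sscparc evaluate --labels sim/sub-00_ssc.nii.gz --atlas sim/sub-00_prior.nii.gz \
    --fmri sim/sub-00_fmri.nii.gz --mask sim/sub-00_mask.nii.gz \
    --out sim/metrics.json
```

Or run the full 20-subject synthetic pipeline (simulate → ReHo → priors →
SSC and NCUT → per-subject metrics → group probability maps, MPM, entropy):

```sh
sscparc run --out run20 --subjects 20 --seed 1
```

which prints (abridged):

```json
{
  "n_subjects": 20,
  "entropy_ssc": 0.315,
  "entropy_ncut": 0.291,
  "mean_dice_ssc_vs_atlas": 0.807,
  "mean_dice_ncut_vs_atlas": 0.767,
  "mean_si_ssc": 0.362,
  "mean_si_atlas": 0.209,
  "mpm_volume_mm3": 1863.0
}
```

Reading these numbers: the SSC parcellation overlaps the anatomical atlas
more than the unsupervised baseline does (Dice 0.81 vs 0.77) and is more
functionally homogeneous than the atlas itself (silhouette 0.36 vs 0.21).
Cross-subject entropy (lower = more consistent) is near the floor set by
the simulated inter-subject boundary jitter for both methods at this
signal-to-noise level; the prior's consistency advantage grows as the
functional signal weakens (see `docs/methods.md`). The maximum probability
map volume (~1.9 cm³ at 1.5 mm isotropic voxels) is the group-level
parcel footprint.

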