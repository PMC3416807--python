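# Methods

## The estimation chain

`alemeta` treats a meta-analytic corpus as a set of *experiments*, each
an ordered list of activation peaks in a single consistent millimeter
space (MNI convention; no Talairach conversion is attempted — all
inputs are assumed to share one space). All maps live on a regular,
axis-aligned voxel grid with a diagonal affine; public APIs speak
millimeters only.

**Kernel.** Every focus is modeled as an isotropic 3-D Gaussian
probability distribution with fixed FWHM (default 10 mm, the
convention of the classical ALE literature), evaluated at voxel
centers, multiplied by the voxel volume and renormalized to unit mass
over the in-mask grid. The renormalization makes the per-focus map a
proper probability distribution on the mask regardless of mask
truncation. No per-study subject-count adaptation of the kernel is
performed: all experiments receive the same width.

**Statistic.** Foci within an experiment combine into a
modeled-activation (MA) map by probabilistic union, and MA maps
combine across experiments the same way (`ale_map`). The grouped form
is the default; `group_by_experiment=False` gives the older pure
per-focus union, in which an experiment with many foci carries more
weight. Both are unions of independent events, so the statistic is
monotone in the corpus and invariant to experiment and focus order.

**Null and thresholding.** The null relocates every focus
independently and uniformly over in-mask voxel centers, preserving
per-experiment focus counts, and pools all in-mask voxel values of the
recomputed ALE maps over `n_permutations` randomizations
(pooled-voxel null). Because relocation is exchangeable across
voxels, the pooled marginal equals the per-voxel null. Empirical
p-values use the add-one convention p = (1 + #null ≥ obs)/(1 + N), so
p is never 0 and an observed 0 gets p = 1. Voxelwise p-values are
corrected by Benjamini–Hochberg step-up at level `q_fdr` (ties share
the decision of their largest index, the standard largest-k rule);
surviving voxels are grouped into connected components
(26-connectivity by default, 6 available) and components must
*strictly* exceed `min_cluster_mm3` to survive — on a 2 mm grid,
a 12-voxel component (96 mm³) dies and a 13-voxel component (104 mm³)
lives against the 100 mm³ default.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| `fwhm` | mm | 10 | classical fixed-width ALE kernel |
| `n_permutations` | — | 1000 (200 in desk-scale runs) | p-value floor 1/(N·V+1) is far below any BH cutoff already at 200 |
| `q_fdr` | — | 0.05 | conventional FDR level |
| `min_cluster_mm3` | mm³ | 100 | strict `> 100 mm³` extent rule |
| `connectivity` | — | 26 | common neuroimaging component rule |
| grid | mm | 2 isotropic | standard analysis resolution; keeps the extent rule meaningful (100 mm³ = 12.5 voxels) |

## Downstream operations

**Overlap and conjunction.** Inputs are binarized thresholded maps;
the overlap value at a voxel is the exact count of active networks
divided by N, and the conjunction demands the integer count equal N —
a logical AND with no float tolerance. Averaging raw statistic values
instead of binary membership is available (`binarize=False`) but the
strict conjunction is only defined on the binary reading. Low-overlap
extraction works on whole value strata, admitted low-to-high while the
cumulative voxel count stays within ceil(fraction × n_nonzero); the
first stratum that would overshoot is excluded entirely, so tied
voxels never split. If all nonzero voxels share one value no
selection is possible and the whole stratum is returned with a
warning.

**MACM.** An experiment qualifies if at least one focus's nearest
voxel lies in at least one seed ROI (logical OR across ROIs; a
`require_all` flag implements the AND reading, since both readings
appear in the MACM literature). Membership uses nearest-voxel lookup
without dilation; `dilate_mm` pads ROIs via a Euclidean distance
transform for the common practice of padding small seeds. The
selected subset then runs through the full ALE chain.

**Similarity.** Unthresholded ALE maps are vectorized over the shared
mask (thresholding first would make 1 − r degenerate for sparse maps;
a caller can of course pass thresholded maps). Distances are 1 −
Pearson r — Pearson, not rank, matching the representational-
similarity convention for continuous maps. Matrix reordering is
spectral: networks are sorted by the Fiedler vector of the graph
Laplacian of the similarity matrix (negative similarities clipped to
zero edge weight), with the eigenvector's global sign fixed by its
first nonzero entry; exhaustive ordering is factorial and is used only
as a test oracle at small n. Ward linkage operates on the 1 − r
dissimilarities directly (Ward.D convention; `squared=True` gives the
squared-input variant — the literature is split and neither is
canonical for correlation distances). MDS is classical/Torgerson —
double-centering of squared dissimilarities and a top-d spectral
embedding, with normalized residual stress √(Σ(d̂ − D)²/ΣD²); an
iterative stress-minimizing refinement was deliberately not added
since the classical solution is exact on Euclidean input and
deterministic.

**Term statistics.** The study corpus is a binary study × term and
study × region incidence table. Association is the natural log of the
Jaccard index over study sets (lnJ = −∞ for disjoint sets, kept as a
sentinel rather than an error); phenotype maps threshold at lnJ > −10
by default. Forward inference is a direct conditional frequency;
reverse inference applies Bayes' rule with either the empirical term
base rate (in which case it reduces exactly to
count(term ∧ act)/count(act), a consistency the tests assert) or a
user prior such as 0.5. Voxels with zero activation probability under
the prior yield NaN, never a silent 0.

## The synthetic generator

The generator emulates a database query result, not a brain: each
network scatters foci around planted true centers with isotropic
Gaussian jitter (matching the kernel's own spatial-uncertainty model,
which keeps recovery interpretable), plus a fraction of uniform noise
foci inside the mask. Defaults define the reference study conditions:
8 networks × 15 experiments × 10 foci, jitter sd 4 mm, noise fraction
0.2 (one in five reported peaks treated as non-network noise — a
realistic contamination level for behavioral-domain queries), on a
64 mm cubic mask of 2 mm voxels. Every network shares one hub center
and keeps one private center, with private centers separated by more
than 4× the jitter sd. Two further planted designs serve the
connectivity and similarity stages: a co-activation design (half the
experiments carry hub + region B, half carry only control region C)
and a two-group design (two quartets of networks with group-shared
centers plus one dual-membership reference network). Study corpora
for inference are sampled from explicit conditionals
P(act|term)/P(act|¬term).

What the generator does *not* emulate: anatomical structure, mask
irregularity, between-study variation in focus counts, spatially
correlated noise, publication bias, or text-mining noise in term
tags. Passing tests therefore demonstrate algorithmic correctness and
recovery of planted structure under idealized sampling — not
performance on real database holdings.

## Numerical and degenerate-input choices

* Foci outside the mask are flagged into a QC report and excluded from
  kernels, never silently dropped; an experiment with no in-mask focus
  drops out of the analysis but stays in the report.
* Jittered foci are rejection-sampled until inside the mask, so
  empirical moments are very slightly truncated near mask edges.
* `NullDistribution` stores the sorted pooled sample; p-values are
  vectorized binary searches.
* Constant (zero-variance) map vectors are rejected by name rather
  than producing NaN correlations.
* All randomness flows through `numpy.random.default_rng` seeds;
  scenario builders derive per-network seeds via `SeedSequence.spawn`,
  so collections are independent but fully reproducible.
* Pipeline reruns with the same configuration are byte-identical,
  including `.nii.gz` outputs (nibabel writes deterministic gzip
  headers); the provenance report records parameters, per-stage wall
  time and a sha256 per output file.

## Pipeline configuration

`ale pipeline --config study.yaml --out outdir/` accepts a flat YAML
file with optional sections `scenario` (n_networks, n_experiments,
foci_per_experiment, jitter_sd, noise_fraction, seed, grid.n,
grid.voxel_size — or `synthetic: false` with `foci_files`), `ale`
(fwhm, n_permutations, q_fdr, min_cluster_mm3, connectivity),
`overlap` (low_fraction), `macm` (enabled, require_all, dilate_mm),
`rsa` (enabled, reference) and `corpus` (enabled, n_studies, terms,
p_term, p_act_given_term, p_act_given_notterm, threshold_lnj,
reverse_threshold). Omitted keys fall back to the defaults in
`alemeta.pipeline.default_config`.

## Known limitations

* Voxelwise-FDR ALE extents scale with kernel width and evidence
  strength, not with the spatial scatter of the underlying foci: with
  15 experiments repeatedly hitting the same center, voxels remain
  significant out to roughly twice the kernel σ from the center. The
  conjunction of such maps is therefore a faithful but *generous*
  localization of a planted hub — its area is several times the
  jitter-scale sphere, which callers should keep in mind when
  comparing conjunction regions against compact anatomical priors
  (the acceptance script reports the measured Dice for exactly this
  comparison).
* Only diagonal affines (axis-aligned grids) are supported; no
  resampling, no Talairach↔MNI conversion.
* No cluster-level familywise-error inference; thresholding is
  voxelwise FDR plus a cluster-extent floor.
* The reverse-inference prior for historical database frameworks is
  not uniquely documented; both empirical and uniform priors are
  provided and the choice is explicit in every API.
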