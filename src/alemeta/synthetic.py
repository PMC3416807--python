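"""Synthetic foci corpora and study corpora with planted ground truth.

Real coordinate-based meta-analyses draw on curated databases of
activation peaks; those holdings are proprietary and unversioned, so
every downstream stage here is exercised on generated corpora whose
structure is known exactly: each task network scatters foci (isotropic
Gaussian jitter) around planted true centers, a configurable fraction
of foci is uniform noise inside the mask, and one planted "hub" center
is shared by all networks while each network keeps a private center of
its own.  Term/activation incidence corpora for Bayesian inference are
sampled from explicit conditional probabilities.

Jitter is isotropic Gaussian to match the spatial-uncertainty model of
the ALE kernel itself, which keeps parameter recovery interpretable.
The default desk-scale scenario is 8 networks x 15 experiments x 10
foci on a 2 mm grid over a 64 mm cubic mask: the full pipeline runs in
seconds to minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Focus, FociExperiment, NetworkCollection, VolumeMap
from .terms import StudyCorpus

__all__ = [
    "NetworkSpec",
    "CorpusSpec",
    "default_mask",
    "generate_network",
    "generate_hub_scenario",
    "default_hub_specs",
    "macm_scenario",
    "two_group_scenario",
    "sphere_roi",
    "generate_corpus",
]

#: Default planted-structure conditions: 8 networks, 15 experiments of
#: 10 foci each, 4 mm jitter, 20% uniform noise foci.
N_NETWORKS = 8
N_EXPERIMENTS = 15
FOCI_PER_EXPERIMENT = 10
JITTER_SD = 4.0
NOISE_FRACTION = 0.2
HUB_CENTER = (0.0, 0.0, 0.0)

#: Private centers for the default 8-network scenario: cube corners at
#: |18| mm, pairwise >= 36 mm apart and ~31 mm from the central hub —
#: comfortably beyond 4x the default jitter.
_PRIVATE_CENTERS = [
    (-18.0, -18.0, -18.0),
    (18.0, -18.0, -18.0),
    (-18.0, 18.0, -18.0),
    (18.0, 18.0, -18.0),
    (-18.0, -18.0, 18.0),
    (18.0, -18.0, 18.0),
    (-18.0, 18.0, 18.0),
    (18.0, 18.0, 18.0),
]


def default_mask(n: int = 32, voxel_size: float = 2.0) -> VolumeMap:
    """All-true cubic mask: n^3 voxels of ``voxel_size`` mm, centered on 0."""
    half = voxel_size * (n - 1) / 2.0
    return VolumeMap(
        np.zeros((n, n, n)),
        voxel_size=voxel_size,
        origin=(-half, -half, -half),
        mask=np.ones((n, n, n), dtype=bool),
    )


@dataclass
class NetworkSpec:
    """Recipe for one synthetic task network."""

    name: str
    true_centers: list[tuple[float, float, float]]
    jitter_sd: float = JITTER_SD
    n_experiments: int = N_EXPERIMENTS
    foci_per_experiment: int = FOCI_PER_EXPERIMENT
    noise_fraction: float = NOISE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.jitter_sd <= 0:
            raise ValueError("jitter_sd must be positive")
        if self.n_experiments < 1 or self.foci_per_experiment < 1:
            raise ValueError("counts must be >= 1")
        if not self.true_centers:
            raise ValueError("at least one true center required")


def _uniform_in_mask(rng: np.random.Generator, mask_map: VolumeMap, n: int) -> np.ndarray:
    """n points uniform over the mask volume: random in-mask voxel plus
    a uniform offset within that voxel."""
    idx = np.argwhere(mask_map.mask)
    picks = idx[rng.integers(0, len(idx), size=n)]
    centers = mask_map.voxel_to_mm(picks)
    offsets = rng.uniform(-0.5, 0.5, size=(n, 3)) * mask_map.voxel_size
    return centers + offsets


def _jittered_focus(rng: np.random.Generator, center: np.ndarray, sd: float, mask_map: VolumeMap) -> np.ndarray:
    # rejection-sample so every retained focus lies inside the mask
    for _ in range(1000):
        pt = center + rng.normal(0.0, sd, size=3)
        if mask_map.in_mask(pt):
            return pt
    raise RuntimeError("could not place a jittered focus inside the mask")


def generate_network(spec: NetworkSpec, mask_map: VolumeMap) -> NetworkCollection:
    """Sample one network's experiments.

    Each experiment draws ``round(noise_fraction * foci_per_experiment)``
    noise foci uniform over the mask; the remaining foci cycle through
    ``true_centers`` (so every center is used at least once whenever the
    signal-focus count is >= the number of centers) with isotropic
    Gaussian jitter of sd ``jitter_sd``.  Deterministic given the seed.
    """
    centers = [np.asarray(c, dtype=float) for c in spec.true_centers]
    for c in centers:
        if not mask_map.in_mask(c):
            raise ValueError(f"true center {tuple(c)} outside mask")
    rng = np.random.default_rng(spec.seed)
    n_noise = int(round(spec.noise_fraction * spec.foci_per_experiment))
    n_signal = spec.foci_per_experiment - n_noise
    experiments = []
    for e in range(spec.n_experiments):
        foci: list[Focus] = []
        for k in range(n_signal):
            pt = _jittered_focus(rng, centers[k % len(centers)], spec.jitter_sd, mask_map)
            foci.append(Focus(*pt))
        if n_noise:
            for pt in _uniform_in_mask(rng, mask_map, n_noise):
                foci.append(Focus(*pt))
        experiments.append(
            FociExperiment(
                experiment_id=f"{spec.name}-exp{e:03d}",
                study_id=f"{spec.name}-study{e:03d}",
                foci=foci,
                domain_labels={spec.name},
                subject_group="Normal subjects",
            )
        )
    return NetworkCollection(name=spec.name, experiments=experiments)


def default_hub_specs(
    n_networks: int = N_NETWORKS,
    hub_center=HUB_CENTER,
    jitter_sd: float = JITTER_SD,
    n_experiments: int = N_EXPERIMENTS,
    foci_per_experiment: int = FOCI_PER_EXPERIMENT,
    noise_fraction: float = NOISE_FRACTION,
    seed: int = 0,
) -> list[NetworkSpec]:
    """Per-network specs for the planted-hub scenario."""
    if n_networks > len(_PRIVATE_CENTERS):
        raise ValueError(f"at most {len(_PRIVATE_CENTERS)} networks supported by default centers")
    child_seeds = np.random.SeedSequence(seed).spawn(n_networks)
    specs = []
    for i in range(n_networks):
        specs.append(
            NetworkSpec(
                name=f"net{i:02d}",
                true_centers=[tuple(hub_center), _PRIVATE_CENTERS[i]],
                jitter_sd=jitter_sd,
                n_experiments=n_experiments,
                foci_per_experiment=foci_per_experiment,
                noise_fraction=noise_fraction,
                seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            )
        )
    return specs


def generate_hub_scenario(
    n_networks: int = N_NETWORKS,
    hub_center=HUB_CENTER,
    per_network_specs: list[NetworkSpec] | None = None,
    mask_map: VolumeMap | None = None,
    seed: int = 0,
    **spec_overrides,
) -> list[NetworkCollection]:
    """Generate the planted-hub scenario.

    Every network's center list contains ``hub_center``; each also has a
    private center absent from all other networks, with pairwise private
    distances > 4x the jitter sd.
    """
    if mask_map is None:
        mask_map = default_mask()
    if per_network_specs is None:
        per_network_specs = default_hub_specs(
            n_networks=n_networks, hub_center=hub_center, seed=seed, **spec_overrides
        )
    hub = np.asarray(hub_center, dtype=float)
    for spec in per_network_specs:
        if not any(np.allclose(hub, c) for c in spec.true_centers):
            raise ValueError(f"spec {spec.name!r} does not include the hub center")
    privates = [
        np.asarray(c)
        for spec in per_network_specs
        for c in spec.true_centers
        if not np.allclose(np.asarray(c, dtype=float), hub)
    ]
    for i in range(len(privates)):
        for j in range(i + 1, len(privates)):
            d = float(np.linalg.norm(privates[i] - privates[j]))
            min_sep = 4.0 * max(s.jitter_sd for s in per_network_specs)
            if d <= min_sep:
                raise ValueError(f"private centers {i} and {j} too close ({d:.1f} mm <= {min_sep:.1f} mm)")
    return [generate_network(spec, mask_map) for spec in per_network_specs]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def sphere_roi(mask_map: VolumeMap, center, radius_mm: float) -> VolumeMap:
    """Binary sphere ROI: voxels whose center lies within radius_mm."""
    xs, ys, zs = mask_map.axis_coords()
    c = np.asarray(center, dtype=float)
    d2 = (
        (xs - c[0])[:, None, None] ** 2
        + (ys - c[1])[None, :, None] ** 2
        + (zs - c[2])[None, None, :] ** 2
    )
    return mask_map.like((d2 <= radius_mm**2).astype(float))


def macm_scenario(mask_map: VolumeMap | None = None, seed: int = 0) -> dict:
    """Planted co-activation design for seed-based connectivity tests.

    Half the experiments ("coact") report foci at the hub *and* at a
    co-planted region B; the other half ("ctrl") report only at a
    control region C.  Seeding a meta-analytic connectivity analysis at
    the hub should select exactly the coact experiments and recover B
    but not C.  Noise fraction is 0 so selection has a clean truth.
    """
    if mask_map is None:
        mask_map = default_mask()
    hub, region_b, region_c = (0.0, 0.0, 0.0), (-20.0, 0.0, 0.0), (20.0, 0.0, 0.0)
    s1, s2 = _seeds(seed, 2)
    coact = generate_network(
        NetworkSpec("coact", [hub, region_b], jitter_sd=JITTER_SD, n_experiments=10,
                    foci_per_experiment=12, noise_fraction=0.0, seed=s1),
        mask_map,
    )
    ctrl = generate_network(
        NetworkSpec("ctrl", [region_c], jitter_sd=JITTER_SD, n_experiments=10,
                    foci_per_experiment=12, noise_fraction=0.0, seed=s2),
        mask_map,
    )
    return {
        "coactivating": coact,
        "control": ctrl,
        "hub": hub,
        "region_b": region_b,
        "region_c": region_c,
        "seed_roi": sphere_roi(mask_map, hub, 8.0),
        "mask": mask_map,
    }


#: Centers for the planted two-group similarity design: two shared
#: centers per group plus one private center per network.
_GROUP_A_CENTERS = [(-14.0, -14.0, -14.0), (-14.0, 14.0, 0.0)]
_GROUP_B_CENTERS = [(14.0, 14.0, 14.0), (14.0, -14.0, 0.0)]
_TG_PRIVATE = [
    (-22.0, 0.0, 14.0),
    (0.0, -22.0, -14.0),
    (-8.0, 22.0, 18.0),
    (22.0, 8.0, -18.0),
    (8.0, -8.0, 22.0),
    (-18.0, -4.0, 20.0),
    (4.0, 18.0, -22.0),
    (18.0, -18.0, 8.0),
]


def two_group_scenario(
    mask_map: VolumeMap | None = None, seed: int = 0, include_reference: bool = True
) -> list[NetworkCollection]:
    """Planted two-cluster design for similarity/clustering tests.

    Four "affective-like" networks share one pair of centers, four
    "sensorimotor-like" networks share another pair, and each network
    adds a private center.  The optional ninth "ref" network shares one
    center with each group, so it sits between the clusters and has the
    minimal mean 1-r distance to all others.
    """
    if mask_map is None:
        mask_map = default_mask()
    n = 9 if include_reference else 8
    seeds = _seeds(seed, n)
    specs = []
    for i in range(4):
        specs.append(
            NetworkSpec(f"aff{i}", _GROUP_A_CENTERS + [_TG_PRIVATE[i]], jitter_sd=JITTER_SD,
                        n_experiments=5, foci_per_experiment=8, noise_fraction=0.1, seed=seeds[i])
        )
    for i in range(4):
        specs.append(
            NetworkSpec(f"sens{i}", _GROUP_B_CENTERS + [_TG_PRIVATE[4 + i]], jitter_sd=JITTER_SD,
                        n_experiments=5, foci_per_experiment=8, noise_fraction=0.1, seed=seeds[4 + i])
        )
    if include_reference:
        specs.append(
            NetworkSpec("ref", [_GROUP_A_CENTERS[0], _GROUP_B_CENTERS[0]], jitter_sd=JITTER_SD,
                        n_experiments=5, foci_per_experiment=8, noise_fraction=0.1, seed=seeds[8])
        )
    return [generate_network(s, mask_map) for s in specs]


# ---------------------------------------------------------------------
# Study corpora for forward/reverse inference
# ---------------------------------------------------------------------


@dataclass
class CorpusSpec:
    """Recipe for a binary study x term / study x region corpus.

    Activation of the designated ``target_region`` depends on
    ``target_term`` through ``p_act_given_term`` / ``p_act_given_notterm``;
    background regions activate at ``p_act_background`` regardless of
    terms, modeling non-selective areas.
    """

    n_studies: int
    terms: list[str]
    p_term: dict[str, float] | float = 0.3
    p_act_given_term: float = 0.8
    p_act_given_notterm: float = 0.1
    target_term: str | None = None
    target_region: str = "target"
    n_background_regions: int = 3
    p_act_background: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_term is None:
            self.target_term = self.terms[0]
        probs = [self.p_act_given_term, self.p_act_given_notterm, self.p_act_background]
        if isinstance(self.p_term, dict):
            probs += list(self.p_term.values())
        else:
            probs.append(self.p_term)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.target_term not in self.terms:
            raise ValueError("target_term must be among terms")

    def term_rate(self, term: str) -> float:
        if isinstance(self.p_term, dict):
            return self.p_term[term]
        return self.p_term


def generate_corpus(spec: CorpusSpec) -> StudyCorpus:
    """Sample a :class:`~alemeta.terms.StudyCorpus`; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    study_ids = [f"s{i:05d}" for i in range(spec.n_studies)]
    term_mat = np.column_stack(
        [rng.random(spec.n_studies) < spec.term_rate(t) for t in spec.terms]
    ).astype(int)
    has_term = term_mat[:, spec.terms.index(spec.target_term)].astype(bool)
    p_act = np.where(has_term, spec.p_act_given_term, spec.p_act_given_notterm)
    regions = [spec.target_region] + [f"bg{i:02d}" for i in range(spec.n_background_regions)]
    act_cols = [(rng.random(spec.n_studies) < p_act).astype(int)]
    for _ in range(spec.n_background_regions):
        act_cols.append((rng.random(spec.n_studies) < spec.p_act_background).astype(int))
    act_mat = np.column_stack(act_cols)
    return StudyCorpus.from_arrays(study_ids, spec.terms, term_mat, regions, act_mat)
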