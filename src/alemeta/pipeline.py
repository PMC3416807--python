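"""One-command orchestration of the full meta-analysis at desk scale.

``run_study`` drives: synthetic corpus generation (or foci files) →
per-network ALE + permutation thresholding → probability overlap,
conjunction and low-overlap maps → MACM seeded at the conjunction →
representational similarity (distances, spectral reordering, Ward
dendrogram, classical MDS, reference profile) → term statistics if a
corpus section is configured.  Every output lands in one directory
with a JSON provenance report (parameters, seed, per-stage wall time,
sha256 of every written file).

Configuration is a flat YAML file with per-stage sections; every
section is optional and falls back to the defaults documented in
:func:`default_config`.  Any stage failure aborts with the stage name;
the partial report is retained with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ale import AleParams, ale_map, build_null, threshold_map
from .corpus_io import read_foci_table, write_volume
from .macm import macm_map
from .overlap import conjunction, low_overlap_region, probability_overlap
from .similarity import (
    centrality_profile,
    cut_dendrogram,
    distance_matrix,
    linkage_to_tree,
    mds_embed,
    mean_distances,
    reorder_matrix,
    vectorize_maps,
    ward_dendrogram,
)
from .synthetic import CorpusSpec, default_mask, generate_corpus, generate_hub_scenario
from .terms import forward_inference, phenotype_map, reverse_inference, specificity_overlap

__all__ = ["PipelineError", "default_config", "run_study"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config(seed: int = 0) -> dict:
    """Default synthetic desk-scale study configuration."""
    return {
        "scenario": {
            "synthetic": True,
            "n_networks": 8,
            "n_experiments": 15,
            "foci_per_experiment": 10,
            "jitter_sd": 4.0,
            "noise_fraction": 0.2,
            "grid": {"n": 32, "voxel_size": 2.0},
            "seed": seed,
        },
        "ale": {
            "fwhm": 10.0,
            "n_permutations": 200,
            "q_fdr": 0.05,
            "min_cluster_mm3": 100.0,
            "connectivity": 26,
        },
        "overlap": {"low_fraction": 0.2},
        "macm": {"enabled": True, "require_all": False, "dilate_mm": 0.0},
        "rsa": {"enabled": True, "reference": None},
        "corpus": {
            "enabled": True,
            "n_studies": 500,
            "terms": ["pain", "attention", "emotion"],
            "p_term": 0.3,
            "p_act_given_term": 0.8,
            "p_act_given_notterm": 0.1,
            "threshold_lnj": -10.0,
            "reverse_threshold": 0.5,
        },
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_study(config, out_dir) -> dict:
    """Run the configured study end to end; returns the report dict.

    ``config`` is a dict or a path to a YAML file; missing keys fall
    back to :func:`default_config`.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(default_config(), config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": cfg,
        "stages": [],
        "outputs": {},
    }

    def _write_map(vmap, name):
        path = out / name
        write_volume(vmap, path)
        report["outputs"][name] = _sha256(path)

    def _write_text(text, name):
        path = out / name
        path.write_text(text)
        report["outputs"][name] = _sha256(path)

    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # abort with the failing stage's name
            report["failed_stage"] = name
            (out / "report.partial.json").write_text(json.dumps(report, indent=2, default=str))
            raise PipelineError(name, exc) from exc
        report["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})

    # -- generate / load ----------------------------------------------
    def s_inputs():
        sc = cfg["scenario"]
        grid_cfg = sc.get("grid", {})
        state["grid"] = default_mask(n=grid_cfg.get("n", 32), voxel_size=grid_cfg.get("voxel_size", 2.0))
        if sc.get("synthetic", True):
            state["networks"] = generate_hub_scenario(
                n_networks=sc["n_networks"],
                mask_map=state["grid"],
                seed=sc["seed"],
                jitter_sd=sc["jitter_sd"],
                n_experiments=sc["n_experiments"],
                foci_per_experiment=sc["foci_per_experiment"],
                noise_fraction=sc["noise_fraction"],
            )
        else:
            from .corpus_io import NetworkCollection

            state["networks"] = [
                NetworkCollection(name=name, experiments=read_foci_table(path, sc.get("dialect", "sleuth_text")))
                for name, path in sc["foci_files"].items()
            ]

    stage("inputs", s_inputs)

    # -- per-network ALE ----------------------------------------------
    def s_ale():
        sc_seed = cfg["scenario"]["seed"]
        state["ale_maps"], state["thresholded"] = {}, {}
        for i, net in enumerate(state["networks"]):
            params = AleParams(seed=(sc_seed * 1009 + i) % (2**31), **cfg["ale"])
            amap = ale_map(net.experiments, params, state["grid"])
            null = build_null(net.experiments, params, state["grid"])
            tmap = threshold_map(amap, null, params)
            state["ale_maps"][net.name] = amap
            state["thresholded"][net.name] = tmap
            _write_map(amap, f"ale_{net.name}.nii.gz")
            _write_map(tmap, f"thresh_{net.name}.nii.gz")

    stage("ale", s_ale)

    # -- overlap / conjunction ----------------------------------------
    def s_overlap():
        names = [n.name for n in state["networks"]]
        ov = probability_overlap([state["thresholded"][n] for n in names], names)
        conj = conjunction(ov)
        low = low_overlap_region(ov, cfg["overlap"]["low_fraction"])
        state["overlap"], state["conjunction"], state["low"] = ov, conj, low
        _write_map(ov, "overlap.nii.gz")
        _write_map(conj, "conjunction.nii.gz")
        _write_map(low, "low_overlap.nii.gz")

    stage("overlap", s_overlap)

    # -- MACM seeded at the conjunction -------------------------------
    if cfg["macm"]["enabled"]:

        def s_macm():
            all_exps = [e for net in state["networks"] for e in net.experiments]
            params = AleParams(seed=(cfg["scenario"]["seed"] * 1013 + 999) % (2**31), **cfg["ale"])
            tmap, prov = macm_map(
                all_exps,
                [state["conjunction"]],
                params,
                state["grid"],
                require_all=cfg["macm"]["require_all"],
                dilate_mm=cfg["macm"]["dilate_mm"],
            )
            state["macm"] = tmap
            prov.pop("ale_map")
            report["macm"] = {k: v for k, v in prov.items() if k != "selection_report"}
            report["macm"]["n_matching_experiments"] = len(prov["selection_report"])
            _write_map(tmap, "macm.nii.gz")

        stage("macm", s_macm)

    # -- representational similarity ----------------------------------
    if cfg["rsa"]["enabled"]:

        def s_rsa():
            names = [n.name for n in state["networks"]]
            vectors = vectorize_maps([state["ale_maps"][n] for n in names], names)
            dm = distance_matrix(vectors, names)
            order = reorder_matrix(dm)
            Z = ward_dendrogram(dm)
            clusters = cut_dendrogram(Z, dm, n_clusters=2)
            emb = mds_embed(dm, d=min(2, dm.n - 1))
            reference = cfg["rsa"]["reference"] or names[0]
            profile = centrality_profile(dm, reference)
            state["distance_matrix"] = dm
            _write_text(dm.to_frame().to_csv(sep="\t"), "distance_matrix.tsv")
            _write_text(json.dumps(linkage_to_tree(Z, dm.labels), indent=2), "dendrogram.json")
            _write_text(
                "\n".join(
                    lab + "\t" + "\t".join(f"{c:.6f}" for c in row)
                    for lab, row in zip(emb.labels, emb.coords)
                )
                + "\n",
                "mds_coords.tsv",
            )
            _write_text(profile.to_csv(sep="\t", index=False), "reference_profile.tsv")
            report["rsa"] = {
                "reordering": [dm.labels[i] for i in order],
                "clusters": clusters,
                "mds_stress": emb.stress,
                "mean_distances": mean_distances(dm).round(6).to_dict(),
            }

        stage("rsa", s_rsa)

    # -- term statistics ----------------------------------------------
    if cfg["corpus"]["enabled"]:

        def s_terms():
            cc = cfg["corpus"]
            spec = CorpusSpec(
                n_studies=cc["n_studies"],
                terms=list(cc["terms"]),
                p_term=cc["p_term"],
                p_act_given_term=cc["p_act_given_term"],
                p_act_given_notterm=cc["p_act_given_notterm"],
                seed=cfg["scenario"]["seed"],
            )
            corpus = generate_corpus(spec)
            lnj, edges = phenotype_map(corpus, threshold_lnj=cc["threshold_lnj"])
            fwd = forward_inference(corpus, spec.target_term)
            rev = reverse_inference(corpus, spec.target_term)
            _write_text(lnj.to_csv(sep="\t"), "lnj_matrix.tsv")
            _write_text(edges.to_csv(sep="\t", index=False), "associations.tsv")
            _write_text(
                fwd.to_frame().join(rev.to_frame()).to_csv(sep="\t"), "inference_maps.tsv"
            )
            target_active = (rev > cc["reverse_threshold"]).astype(float).to_numpy()
            truth = np.array([1.0] + [0.0] * (len(rev) - 1))  # target region first
            report["terms"] = {
                "target_term": spec.target_term,
                "forward_target": float(fwd.iloc[0]),
                "reverse_target": float(rev.iloc[0]),
                "specificity_vs_truth": specificity_overlap(
                    target_active, truth, threshold=0.0
                ),
            }

        stage("terms", s_terms)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    return report
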