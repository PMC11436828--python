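"""End-to-end driver: simulate -> fit ladder -> desymmetrize -> hierarchy ->
evaluate -> connectivity, with a deterministic JSON manifest.

The pipeline exists so a whole study can be reproduced from one config and
one seed: every stage draws its randomness from a single generator chain,
the manifest records content hashes of the key arrays, and rerunning with
the same config yields a bit-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from .fusion import fit_fusion, match_parcels
from .hierarchy import (
    boundary_symmetry,
    build_domains,
    colormap_from_similarity,
    merge_until_winners,
    parcel_similarity,
)
from .io import export_atlas, save_model, save_space
from .metrics import DistanceBinning, adjusted_rand_index, dcbc_individual
from .synthetic import make_world


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run.

    Sizes default to a small smoke-scale world; the K ladder lists the
    granularities to fit, the first entry being the primary atlas used for
    desymmetrization, hierarchy and evaluation.
    """

    width: int = 10
    height: int = 10
    K_true: int = 6
    smoothness: float = 2.0
    symmetric: bool = True
    dataset_specs: dict = field(
        default_factory=lambda: {
            "dsA": {"n_subjects": 3, "session_sizes": [8, 8], "kappa": 20.0, "n_runs": 2},
            "dsB": {"n_subjects": 3, "session_sizes": [8, 8], "kappa": 20.0, "n_runs": 2},
        }
    )
    k_ladder: list = field(default_factory=lambda: [6])
    n_starts: int = 5
    max_iter: int = 100
    tol: float = 1e-5
    dcbc_bin_width: float = 1.0
    dcbc_max_dist: float = 35.0
    n_domains: int = 2
    connectivity_lambda: float = 1.0
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory containing the manifest.

    A stage failure leaves earlier outputs in place and records the failed
    stage in the manifest before re-raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    try:
        _run_stages(config, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:  # partial outputs retained
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    seed = int(config.seed)

    # -- simulate ---------------------------------------------------------
    space, truth, datasets = make_world(
        width=config.width,
        height=config.height,
        K=config.K_true,
        smoothness=config.smoothness,
        symmetric=config.symmetric,
        dataset_specs=config.dataset_specs,
        seed=seed,
    )
    save_space(space, out / "world")
    for ds in datasets:
        ds.save(out / "world" / ds.dataset_id)
    manifest["stages"]["simulate"] = {
        "group_prob_hash": _hash(truth.group_prob),
        "data_hashes": {ds.dataset_id: _hash(ds.data) for ds in datasets},
    }

    # -- fit ladder -------------------------------------------------------
    models = {}
    for i, K in enumerate(config.k_ladder):
        models[K] = fit_fusion(
            datasets,
            K=K,
            symmetric=config.symmetric,
            space=space,
            n_starts=config.n_starts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=seed + 1000 + i,
        )
        save_model(models[K], out / f"model_K{K}")
    primary = models[config.k_ladder[0]]
    perm, mean_cos = match_parcels(
        [v for e in primary.emissions.values() for v in e.V],
        [v for ds in datasets for v in truth.true_V[ds.dataset_id]],
    ) if primary.K == truth.K else (None, float("nan"))
    manifest["stages"]["fit"] = {
        str(K): {
            "loglik": models[K].fit_info["loglik"],
            "eta_hash": _hash(models[K].arrangement.eta),
        }
        for K in config.k_ladder
    }
    manifest["stages"]["fit"]["recovery_ari"] = adjusted_rand_index(
        primary.hard_labels(), np.argmax(truth.group_prob, axis=0)
    )
    manifest["stages"]["fit"]["matched_mean_cosine"] = mean_cos

    # -- desymmetrize -----------------------------------------------------
    if config.symmetric:
        asym = primary.desymmetrized(datasets)
        save_model(asym, out / "model_asym")
        bsym = boundary_symmetry(primary, asym, level="group")
        manifest["stages"]["desymmetrize"] = {
            "loglik_sym": primary.log_likelihood(datasets),
            "loglik_asym": asym.log_likelihood(datasets),
            "boundary_symmetry_mean": float(np.nanmean(bsym)),
        }

    # -- hierarchy --------------------------------------------------------
    merged, merge_log = merge_until_winners(primary, datasets)
    sim = parcel_similarity(merged, hemisphere_average=config.symmetric)
    hier = build_domains(sim, min(config.n_domains, sim.shape[0]), model=merged, space=space)
    anchors = {0: (0.0, 0.8, 0.0), sim.shape[0] // 2: (0.8, 0.0, 0.0), sim.shape[0] - 1: (0.8, 0.8, 0.0)}
    if len(set(anchors)) >= 3:
        hier.colors = colormap_from_similarity(sim, anchors)
    export_atlas(merged, out / "atlas", hierarchy=hier)
    manifest["stages"]["hierarchy"] = {
        "K_after_merge": merged.K,
        "n_merges": len(merge_log.merge_tree),
        "domains": [int(d) for d in hier.levels["domain"]],
    }

    # -- evaluate (leave-one-dataset-out individual DCBC) ------------------
    binning = DistanceBinning(space, config.dcbc_bin_width, config.dcbc_max_dist)
    held_out = datasets[-1]
    rest = datasets[:-1]
    loo_model = fit_fusion(
        rest,
        K=config.k_ladder[0],
        symmetric=config.symmetric,
        space=space,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=seed + 2000,
    )
    table = dcbc_individual(loo_model, held_out, space, binning)
    table.to_csv(out / "dcbc_individual.tsv", sep="\t", index=False)
    manifest["stages"]["evaluate"] = {
        "held_out": held_out.dataset_id,
        "dcbc_group_mean": float(table["dcbc_group"].mean()),
        "dcbc_individual_mean": float(table["dcbc_individual"].mean()),
    }

    # -- connectivity ------------------------------------------------------
    W_true, conn_data = conn.make_connectivity_world(seed=seed + 3000)
    models_by_ds = {
        d.dataset_id: conn.fit_subject_models(d, config.connectivity_lambda)
        for d in conn_data
    }
    all_models = [m for ms in models_by_ds.values() for m in ms]
    scores = {
        d.dataset_id: {
            "single": float(
                np.mean(conn.evaluate_connectivity(models_by_ds[d.dataset_id], d))
            ),
            "fused": float(np.mean(conn.evaluate_connectivity(all_models, d))),
        }
        for d in conn_data
    }
    manifest["stages"]["connectivity"] = {"scores": scores, "W_true_hash": _hash(W_true)}
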