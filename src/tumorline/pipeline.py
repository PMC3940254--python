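"""End-to-end orchestration: simulate -> quantify -> features -> variance
decomposition -> classification -> comparison, with a reproducibility
manifest.

The pipeline is driven by a plain dict config (typically loaded from YAML);
`DEFAULT_CONFIG` documents the schema.  Identical config + seed produces
byte-identical result files.
"""

from __future__ import annotations

import copy
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, ihc, io, pet, synthetic, texture, varcomp

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_lines": 14,
        "n_per_line": 5,
        "with_missingness": True,
    },
    "classify": {
        "n_trees": 200,
        "n_repeats": 50,
        "train_fraction": 0.75,
        "stratified": True,
    },
    "sweep": {
        "enabled": False,
        "n_trees": 50,
        "k_min": 1,
        "k_max": 8,
    },
    "phantom_demo": True,
    "correlation_method": "spearman",
    "varcomp_method": "reml",
}

_MODEL_SETS = {
    "pet_params": list(classify.PET_PARAMETERS),
    "pet_params_features": list(classify.PET_PARAMETERS) + ["PET_entropy", "PET_skewness"],
    "ihc_params": list(classify.IHC_PARAMETERS),
    "ihc_params_features": list(classify.IHC_PARAMETERS)
    + [f"{m}_{f}" for m in texture.AREA_MARKERS for f in ("mean", "entropy", "skewness")],
}
_MODEL_SETS["all_params"] = _MODEL_SETS["pet_params"] + _MODEL_SETS["ihc_params"]
_MODEL_SETS["all_params_features"] = (_MODEL_SETS["pet_params_features"]
                                      + _MODEL_SETS["ihc_params_features"])


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults and validate the values."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in merged:
            raise io.SchemaError(f"unknown config key {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise io.SchemaError(f"config key {key!r} must be a mapping")
            for sub, sval in value.items():
                if sub not in merged[key]:
                    raise io.SchemaError(f"unknown config key {key}.{sub}")
                merged[key][sub] = sval
        else:
            merged[key] = value
    cls = merged["classify"]
    if not 0 < cls["train_fraction"] < 1:
        raise io.SchemaError("classify.train_fraction must lie in (0, 1)")
    if cls["n_trees"] < 1 or cls["n_repeats"] < 1:
        raise io.SchemaError("classify.n_trees and n_repeats must be positive")
    sw = merged["sweep"]
    if not 1 <= sw["k_min"] <= sw["k_max"] <= len(classify.IHC_PARAMETERS) - 1:
        raise io.SchemaError("sweep.k_min/k_max outside the valid range")
    if merged["correlation_method"] not in ("spearman", "pearson"):
        raise io.SchemaError("correlation_method must be spearman or pearson")
    if merged["varcomp_method"] not in ("reml", "anova"):
        raise io.SchemaError("varcomp_method must be reml or anova")
    return merged


def _phantom_demo(outdir: Path, seed: int) -> pd.DataFrame:
    """Generate, save and quantify one marker-image and one uptake-volume
    phantom; returns a single-row measurement table."""
    img_spec = synthetic.ImagePhantomSpec(width=128, height=128,
                                          stain_fraction_target=0.3,
                                          n_vessels=5, n_nuclei=50,
                                          necrosis_fraction=0.1, seed=seed)
    image, truth = synthetic.generate_marker_image(img_spec)
    io.write_image(outdir / "phantom_marker.tif", image.pixels)
    io.write_mask(outdir / "phantom_necrosis.png", image.necrosis_mask)

    positive = ihc.segment(image)
    viable = ihc.BinaryMask(truth.viable_mask, pixel_size=img_spec.pixel_size)
    vessel, perfusion = synthetic.vessel_masks(truth, img_spec.pixel_size)
    feats = texture.ihc_features(image)

    vol_spec = synthetic.VolumePhantomSpec(dims=(32, 32, 16),
                                           semi_axes=(6.0, 6.0, 4.0), seed=seed)
    volume, vol_truth = synthetic.generate_uptake_volume(vol_spec)
    io.write_volume(outdir / "phantom_volume.npy", volume)
    suv = pet.to_suv(volume)
    voi = pet.delineate_tumor(suv, pet.VOI(np.ones(vol_spec.dims, bool)))
    suv_max, suv_mean = pet.suv_stats(suv, voi)
    pet_feats = texture.pet_features(suv, voi)

    return pd.DataFrame([{
        "sample_id": "phantom_1",
        "line": "phantom",
        "stain_fraction": ihc.staining_fraction(positive, viable),
        "labeling_index": ihc.labeling_index(truth.nuclei, viable),
        "vascular_density": ihc.vascular_density(vessel, viable),
        "perfused_fraction": ihc.perfused_fraction(vessel, perfusion),
        "marker_mean": feats["mean"],
        "marker_entropy": feats["entropy"],
        "marker_skewness": feats["skewness"],
        "suv_max": suv_max,
        "suv_mean": suv_mean,
        "pet_entropy": pet_feats["entropy"],
        "pet_skewness": pet_feats["skewness"],
    }])


def run_pipeline(config: dict | None = None, outdir: str | Path = "results") -> dict:
    """Run every stage on a synthetic cohort and write the result bundle.

    Emits ``cohort.csv``, ``heterogeneity.csv``, ``correlation.csv``,
    ``accuracy.csv``, ``importance.csv``, ``comparison.json`` (plus
    ``sweep.csv`` when enabled and a phantom-measurement CSV) and returns
    the run manifest, which is also written as ``manifest.json``.
    """
    t0 = time.time()
    cfg = validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    outputs: list[Path] = []
    timings: dict[str, float] = {}

    # simulate ------------------------------------------------------------
    t = time.time()
    spec = synthetic.paper_like_cohort_spec(
        seed=seed, n_lines=cfg["cohort"]["n_lines"],
        n_per_line=cfg["cohort"]["n_per_line"],
        with_missingness=cfg["cohort"]["with_missingness"])
    table, truth = synthetic.generate_cohort(spec)
    outputs.append(io.write_feature_table(outdir / "cohort.csv", table))
    io.write_json(outdir / "cohort_truth.json", {
        "true_ratios": truth.ratios,
        "missing_rows": {k: v.tolist() for k, v in truth.missing_rows.items()},
    })
    outputs.append(outdir / "cohort_truth.json")
    timings["simulate"] = time.time() - t

    # quantify + features demo on image/volume phantoms -------------------
    if cfg["phantom_demo"]:
        t = time.time()
        demo = _phantom_demo(outdir, seed)
        outputs.append(io.write_feature_table(outdir / "phantom_measurements.csv", demo))
        timings["phantom_demo"] = time.time() - t

    # variance decomposition ----------------------------------------------
    t = time.time()
    het = varcomp.heterogeneity_table(table, method=cfg["varcomp_method"])
    het.to_csv(outdir / "heterogeneity.csv", index=False)
    outputs.append(outdir / "heterogeneity.csv")
    corr = varcomp.correlation_matrix(table, method=cfg["correlation_method"])
    corr.to_csv(outdir / "correlation.csv")
    outputs.append(outdir / "correlation.csv")
    timings["varcomp"] = time.time() - t

    # classification ------------------------------------------------------
    t = time.time()
    imputed = classify.median_impute(table)
    ccfg = cfg["classify"]
    scheme = classify.make_cv_scheme(imputed, n_repeats=ccfg["n_repeats"],
                                     train_fraction=ccfg["train_fraction"],
                                     seed=seed, stratified=ccfg["stratified"])
    results: dict[str, classify.ModelResult] = {}
    rows = []
    for name, columns in _MODEL_SETS.items():
        result = classify.evaluate_model(imputed, columns, scheme,
                                         n_trees=ccfg["n_trees"], seed=seed,
                                         model_name=name, compute_oob=True)
        results[name] = result
        rows.append({"model": name, "n_columns": len(columns),
                     "oob_accuracy": result.oob_accuracy,
                     "cv_mean": result.mean, "cv_sd": result.sd})
    pd.DataFrame(rows).to_csv(outdir / "accuracy.csv", index=False)
    outputs.append(outdir / "accuracy.csv")

    importance = classify.parameter_importance(imputed, _MODEL_SETS["ihc_params"],
                                               n_trees=ccfg["n_trees"], seed=seed)
    importance.rename_axis("parameter").reset_index().to_csv(
        outdir / "importance.csv", index=False)
    outputs.append(outdir / "importance.csv")
    timings["classify"] = time.time() - t

    # exhaustive IHC subset sweep -----------------------------------------
    if cfg["sweep"]["enabled"]:
        t = time.time()
        per_model, per_k, tests = classify.subset_sweep(
            imputed, k_range=range(cfg["sweep"]["k_min"], cfg["sweep"]["k_max"] + 1),
            scheme=scheme, n_trees=cfg["sweep"]["n_trees"], seed=seed)
        summary = per_k.merge(
            tests.rename(columns={"k_next": "k"})[["k", "mean_diff", "p_value"]],
            on="k", how="left")
        summary.to_csv(outdir / "sweep.csv", index=False)
        outputs.append(outdir / "sweep.csv")
        per_model.to_csv(outdir / "sweep_models.csv", index=False)
        outputs.append(outdir / "sweep_models.csv")
        timings["sweep"] = time.time() - t

    # paired comparison ---------------------------------------------------
    t = time.time()
    comparison = classify.compare_models(results["ihc_params_features"],
                                         results["all_params_features"])
    io.write_json(outdir / "comparison.json", comparison.to_dict())
    outputs.append(outdir / "comparison.json")
    timings["compare"] = time.time() - t

    manifest = {
        "config": cfg,
        "seed": seed,
        "package_version": __import__("tumorline").__version__,
        "outputs": {p.name: io.file_digest(p) for p in outputs},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    io.write_json(outdir / "manifest.json", manifest)
    return manifest
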