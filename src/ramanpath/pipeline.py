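"""End-to-end analysis pipeline: generate -> preprocess -> HCA -> NMF -> PCA
-> markers -> CNN, driven by a JSON-style config with mandatory seeds.

Every stage writes its artifacts into the output directory and appends to
``pipeline.log``; given the same config (including seed) the whole directory
is reproduced deterministically.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import cluster, cnn, io, markers, nuclei_pca, prep, synthgen, unmix
from .core import CLASS_NAMES, Spectrum

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "map": {"class_name": "cPDAC", "width": 24, "height": 24, "noise_sd": 0.02},
    "hca_k": 7,
    "nmf_rank": 3,
    "pca_components": 3,
    "cnn": {"n_per_class": 80, "epochs": 10},
}


def validate_config(config: dict) -> dict:
    """Validate a pipeline config against the documented schema.

    Raises ``ValueError`` before any compute on a violation; returns the
    config merged over the defaults.  A seed is mandatory.
    """
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in config:
        raise ValueError("config must specify a seed (seeds are mandatory)")
    if not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in merged:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            unknown = set(value) - set(merged[key])
            if unknown:
                raise ValueError(f"unknown keys under {key!r}: {sorted(unknown)}")
            merged[key].update(value)
        else:
            merged[key] = value
    cls = merged["map"]["class_name"]
    if cls not in CLASS_NAMES:
        raise ValueError(f"unknown map class {cls!r}")
    for key in ("hca_k", "nmf_rank", "pca_components"):
        if not isinstance(merged[key], int) or merged[key] < 1:
            raise ValueError(f"{key} must be a positive integer")
    return merged


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full demo pipeline; returns the artifact directory."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    log_lines: list[str] = []

    def log(stage: str, **info) -> None:
        line = f"[{stage}] " + json.dumps(info, sort_keys=True)
        log_lines.append(line)

    seed = cfg["seed"]
    log("config", config=cfg)

    # 1. synthetic map -----------------------------------------------------
    t0 = time.time()
    mspec = synthgen.SyntheticTissueSpec(
        map_width=cfg["map"]["width"],
        map_height=cfg["map"]["height"],
        class_name=cfg["map"]["class_name"],
        noise_sd=cfg["map"]["noise_sd"],
        seed=seed,
    )
    hmap = synthgen.generate_tissue_map(mspec)
    io.write_map(out / "map.h5", hmap)
    log("generate", shape=hmap.shape, class_name=mspec.class_name, seed=seed,
        seconds=round(time.time() - t0, 2))

    # 2. preprocessing -----------------------------------------------------
    t0 = time.time()
    pmap = prep.preprocess_map(hmap)
    log("preprocess", axis_points=len(pmap.axis), seconds=round(time.time() - t0, 2))

    # 3. HCA segmentation --------------------------------------------------
    t0 = time.time()
    hres = cluster.hca(pmap, k=cfg["hca_k"])
    io.render_map_png(
        hres.labels - 1,
        palette={i: cluster.DEFAULT_HCA_PALETTE[i] for i in range(cfg["hca_k"])},
        path=out / "hca_map.png",
    )
    mean_matrix = np.vstack(
        [hres.cluster_means[c].intensities for c in sorted(hres.cluster_means)]
    )
    io.write_spectra_csv(out / "hca_means.csv", pmap.axis, mean_matrix)
    log("hca", k=cfg["hca_k"], seconds=round(time.time() - t0, 2))

    # 4. NMF unmixing ------------------------------------------------------
    t0 = time.time()
    cs = unmix.nmf(pmap, rank=cfg["nmf_rank"], seed=seed)
    if cfg["nmf_rank"] >= 3:
        unmix.assign_components(cs)
    io.write_spectra_csv(out / "nmf_components.csv", pmap.axis, cs.component_spectra)
    for i in range(cfg["nmf_rank"]):
        layer = cs.abundance_map(i)
        norm = layer / layer.max() if layer.max() > 0 else layer
        gray = (255 * norm).astype(int)
        io.render_map_png(
            gray, palette={v: (v, v, v) for v in np.unique(gray)},
            path=out / f"nmf_abundance_{i}_{cs.assignments.get(i, 'comp')}.png",
        )
    log("nmf", rank=cfg["nmf_rank"], assignments=cs.assignments,
        rel_error=round(cs.reconstruction_error, 6), seconds=round(time.time() - t0, 2))

    # 5. PCA of nuclei spectra --------------------------------------------
    t0 = time.time()
    means = hres.cluster_means
    nuc_scores = {
        c: unmix._role_score(m.intensities - m.intensities.min(),
                             pmap.axis.wavenumbers, "nucleic_acids")
        for c, m in means.items()
    }
    nuclei_ids = [max(nuc_scores, key=nuc_scores.get)]
    spectra, groups = nuclei_pca.select_nuclei_spectra(pmap, hres.labels, nuclei_ids)
    pca = nuclei_pca.pca_second_derivative(
        spectra, pmap.axis, n_components=cfg["pca_components"], group_labels=groups
    )
    np.savetxt(
        out / "pca_scores.csv",
        np.column_stack([pca.scores, groups]),
        delimiter=",",
        header=",".join(f"PC{i+1}" for i in range(cfg["pca_components"])) + ",group",
        comments="",
        fmt="%.8g",
    )
    log("pca", nuclei_clusters=nuclei_ids, n_spectra=int(spectra.shape[0]),
        explained=[round(float(v), 4) for v in pca.explained_variance_fraction],
        seconds=round(time.time() - t0, 2))

    # 6. markers -----------------------------------------------------------
    t0 = time.time()
    rows = []
    for i in range(cfg["nmf_rank"]):
        s = Spectrum(pmap.axis, cs.component_spectra[i])
        rows.append(
            (
                f"nmf_{i}_{cs.assignments.get(i, 'comp')}",
                markers.beta_sheet_ratio(s, shift_min=True),
                markers.methylation_ratio(s, shift_min=True),
                markers.amide_I_center(s),
            )
        )
    with open(out / "markers.csv", "w") as fh:
        fh.write("spectrum_id,beta_sheet_ratio,methylation_ratio,amide_I_center\n")
        for sid, b, m, a in rows:
            fh.write(f"{sid},{b:.8g},{m:.8g},{a:.8g}\n")
    log("markers", n_rows=len(rows), seconds=round(time.time() - t0, 2))

    # 7. CNN ---------------------------------------------------------------
    t0 = time.time()
    ccfg = cnn.CNNConfig(epochs=cfg["cnn"]["epochs"], seed=seed)
    # Training spectra emulate real map pixels: variable nucleus/cytoplasm
    # mixing, random cubic baselines and the ambient water background.
    training = synthgen.generate_training_set(
        n_per_class=cfg["cnn"]["n_per_class"],
        seed=seed,
        mixture_range=(0.05, 0.95),
        baseline_sd=0.15,
        water_background=0.25,
    )
    dataset = cnn.prepare_dataset(training, ccfg)
    model = cnn.build_model(ccfg)
    history = cnn.train(model, dataset, ccfg)
    pred = cnn.predict_map(model, hmap)
    np.savetxt(out / "prediction_classes.csv", pred.classes, delimiter=",", fmt="%d")
    io.render_map_png(pred.classes, io.CLASS_PALETTE, out / "prediction_map.png")
    agreement = None
    if hmap.class_labels is not None:
        agreement = float(np.mean(pred.classes == hmap.class_labels))
    log("cnn", epochs=ccfg.epochs, final_train_acc=round(history["accuracy"][-1], 4),
        final_val_acc=round(history["val_accuracy"][-1], 4),
        map_agreement=None if agreement is None else round(agreement, 4),
        seconds=round(time.time() - t0, 2))

    log_path.write_text("\n".join(log_lines) + "\n")
    return out
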