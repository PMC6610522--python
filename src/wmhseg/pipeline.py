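"""End-to-end experiment driver: phantom -> IAM -> patches -> train ->
segment -> evaluate, with a manifest that makes the run reconstructible."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import EXPERIMENTS, RunConfig, derive_seed
from .evaluation import confusion_counts, dsc, ppv, sensitivity, wmh_volume
from .io import Volume, write_volume
from .lots_iam import compute_iam
from .models import build_model, count_parameters, save_weights
from .phantom import PhantomBundle, generate_phantom
from .preprocess import (
    brain_tissue_mask,
    extract_training_patches,
    normalize_volume,
)
from .training import predict_volume, train

__all__ = ["run_experiment"]

log = logging.getLogger(__name__)


def _channels_for(bundle: PhantomBundle, layout, iam_map) -> list[Volume]:
    brain = brain_tissue_mask(bundle.icv, bundle.csf)
    out = []
    for name in layout:
        if name == "flair":
            out.append(normalize_volume(bundle.flair, brain))
        elif name == "iam":
            # the irregularity map is already globally normalised to [0, 1]
            out.append(Volume(iam_map, bundle.flair.affine.copy()))
    return out


def run_experiment(config: RunConfig, out_dir) -> pd.DataFrame:
    """Run one experiment end to end and write all artefacts to ``out_dir``.

    Returns the per-scan metrics table (also written as metrics.csv).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fam, layout = EXPERIMENTS[config.experiment]
    needs_iam = "iam" in layout

    def make_scans(n, stage):
        scans = []
        for i in range(n):
            spec = replace(config.phantom, seed=derive_seed(config.seed, stage) + i)
            scans.append(generate_phantom(spec))
        return scans

    log.info("generating %d train / %d test phantoms", config.n_train_scans, config.n_test_scans)
    train_scans = make_scans(config.n_train_scans, "phantom_train")
    test_scans = make_scans(config.n_test_scans, "phantom_test")

    iam_cfg = replace(config.iam, seed=derive_seed(config.seed, "iam"))
    iams = {}
    if needs_iam:
        for tag, scans in (("train", train_scans), ("test", test_scans)):
            for i, b in enumerate(scans):
                log.info("computing IAM for %s scan %d", tag, i)
                iams[(tag, i)] = compute_iam(b.flair, b.icv, b.csf, iam_cfg).final_map

    patches = []
    for i, b in enumerate(train_scans):
        chans = _channels_for(b, layout, iams.get(("train", i)))
        patches.extend(
            extract_training_patches(
                chans,
                b.labels,
                patch_size=config.patch_size,
                n_patches=config.n_patches_per_scan,
                seed=derive_seed(config.seed, "patches") + i,
                wmh_fraction=config.wmh_fraction,
                scan_id=f"train{i}",
            )
        )

    model = build_model(config.architecture(), seed=derive_seed(config.seed, "train"))
    tcfg = replace(config.train, seed=derive_seed(config.seed, "train"))
    model, hist = train(model, patches, tcfg)
    hist.to_frame().to_csv(out / "loss.csv", index=False)
    save_weights(model, out / "weights.npz")

    rows = []
    for i, b in enumerate(test_scans):
        chans = _channels_for(b, layout, iams.get(("test", i)))
        pred, _ = predict_volume(model, chans, tile=config.patch_size)
        write_volume(pred, out / f"pred_test{i}.nii.gz")
        write_volume(b.labels, out / f"truth_test{i}.nii.gz")
        c = confusion_counts(pred, b.labels)
        rows.append(
            {
                "scan": f"test{i}",
                "dsc": dsc(c),
                "sensitivity": sensitivity(c),
                "ppv": ppv(c),
                "true_wmh_volume_mm3": b.true_wmh_volume,
                "pred_wmh_volume_mm3": wmh_volume(pred),
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)

    cfg_dict = asdict(config)
    manifest = {
        "package_version": __version__,
        "experiment": config.experiment,
        "family": fam,
        "parameter_count": count_parameters(model),
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stage_seeds": {s: derive_seed(config.seed, s) for s in
                        ("phantom_train", "phantom_test", "iam", "patches", "train")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return metrics
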