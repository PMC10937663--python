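"""End-to-end pipeline: simulate -> labels -> train -> predict -> metrics.

Mirrors the study's processing flow: phantoms stand in for scans, the
conventional attenuation-compensated thresholding produces the vessel
labels, a U-Net is trained on them, and its predictions on a held-out
volume are compared back to the conventional labels by IOU and vessel
densities.  Every stage logs one structured line with its wall time, and
all outputs carry the configuration hash so a report can be reproduced
from its logged seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import conventional as conv
from . import metrics as met
from . import phantom as ph
from . import unet as un
from .config import RunConfig
from .io import write_mask, write_volume
from .preprocess import normalize_noise
from .volume import OCTVolume

__all__ = ["run_pipeline", "simulate_inputs", "training_set_from_result"]

log = logging.getLogger("octl")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str, t0: float, **params) -> None:
    digest = ", ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s wall_s=%.2f %s", name, time.perf_counter() - t0, digest)


def _phantom_spec(cfg: RunConfig, seed: int, with_layer: bool) -> ph.PhantomSpec:
    p = cfg.phantom
    layer = None
    if with_layer and p.layer_thickness_um:
        layer = ph.SuperficialLayer(p.layer_thickness_um, p.layer_deficit_db)
    return ph.PhantomSpec(
        shape=tuple(p.shape),
        axial_pitch_um=p.axial_pitch_um,
        lateral_pitch_um=tuple(p.lateral_pitch_um),
        refractive_index=p.refractive_index,
        mu_t=p.mu_t,
        source_level_db=p.source_level_db,
        surface_offset_px=p.surface_offset_px,
        surface_tilt_um=tuple(p.surface_tilt_um),
        speckle_contrast=p.speckle_contrast,
        superficial_layer=layer,
        seed=seed,
    )


def simulate_inputs(
    cfg: RunConfig, seed: int
) -> tuple[OCTVolume, OCTVolume, ph.GroundTruth, OCTVolume, ph.GroundTruth]:
    """Calibration scan plus training and held-out eye phantoms."""
    p = cfg.phantom
    cal_spec = ph.PhantomSpec(
        shape=tuple(p.shape),
        axial_pitch_um=p.axial_pitch_um,
        lateral_pitch_um=tuple(p.lateral_pitch_um),
        refractive_index=p.refractive_index,
        mu_t=cfg.conventional.mu_cal,
        source_level_db=p.source_level_db,
        speckle_contrast=p.speckle_contrast,
        seed=seed,
    )
    cal = ph.make_calibration_volume(cal_spec)

    rng = np.random.default_rng(seed + 1)
    train_spec = _phantom_spec(cfg, seed + 2, with_layer=False)
    train_spec = replace(
        train_spec,
        vessels=ph.sample_vessels(
            train_spec, p.n_lymphatic, p.n_vein, rng, deficit_db=p.vessel_deficit_db
        ),
    )
    train_vol, train_truth = ph.make_eye_phantom(train_spec)

    test_spec = _phantom_spec(cfg, seed + 3, with_layer=True)
    test_spec = replace(
        test_spec,
        vessels=ph.sample_vessels(
            test_spec, p.n_lymphatic, p.n_vein, rng, deficit_db=p.vessel_deficit_db
        ),
    )
    test_vol, test_truth = ph.make_eye_phantom(test_spec)
    return cal, train_vol, train_truth, test_vol, test_truth


def training_set_from_result(
    result: conv.ConventionalResult,
) -> tuple[np.ndarray, np.ndarray, float]:
    """8-bit B-scans and binary labels from the conventional output.

    Returns ``(images, labels, vmax)`` with shapes ``(ny, H, W)``; H and W
    are padded up to multiples of 16 so the network accepts them directly.
    """
    vmax = un.volume_vmax(result.volume)
    imgs = un.to_uint8(un.bscans_from_volume(result.volume), vmax)
    labels = np.transpose(result.mask.data, (1, 2, 0))
    imgs, _ = un._pad_to(imgs, 16)
    labels, _ = un._pad_to(labels, 16)
    return imgs, labels.astype(np.float32), vmax


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full flow and write artifacts; returns the report dict."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    seed = config.seed
    report: dict = {"config_hash": chash, "seed": seed}

    t0 = time.perf_counter()
    if config.simulate:
        cal, train_vol, train_truth, test_vol, test_truth = simulate_inputs(config, seed)
    else:
        from .io import read_volume

        if config.volume is None or config.calibration is None:
            missing = "volume" if config.volume is None else "calibration"
            raise ValueError(
                f"config error: '{missing}' input is required when simulate is off"
            )
        train_vol = read_volume(config.volume)
        cal = read_volume(config.calibration)
        test_vol = train_vol
        train_truth = test_truth = None
    _stage("simulate", t0, shape=config.phantom.shape)

    t0 = time.perf_counter()
    if not train_vol.noise_normalized:
        train_vol = normalize_noise(train_vol)
    if not test_vol.noise_normalized:
        test_vol = normalize_noise(test_vol)
    _stage("preprocess", t0)

    t0 = time.perf_counter()
    c = config.conventional
    conv_cfg = conv.ConventionalConfig(
        theta_db=c.theta_db,
        theta_rel_db=c.theta_rel_db,
        crop_um=c.crop_um,
        mu_cal=c.mu_cal,
        speckle_smooth_px=c.speckle_smooth_px,
        canny_sigma=c.canny.sigma,
        canny_low=c.canny.low,
        canny_high=c.canny.high,
        median_width=c.canny.median_width,
        fit=conv.FitPolicy(
            guard_px=c.fit.guard_px,
            noise_margin_db=c.fit.noise_margin_db,
            min_window_px=c.fit.min_window_px,
        ),
    )
    train_res = conv.run_conventional(train_vol, cal, conv_cfg)
    test_res = conv.run_conventional(test_vol, cal, conv_cfg)
    write_mask(train_res.mask, out / "labels_train.tif")
    write_mask(test_res.mask, out / "labels_test.tif")
    write_volume(train_res.volume, out / "aligned_train.tif")
    _stage("conventional", t0, theta_db=round(train_res.theta_db, 2))

    t0 = time.perf_counter()
    imgs, labels, vmax = training_set_from_result(train_res)
    tr, va, te = un.split_dataset(len(imgs), config.train.split, seed=seed)
    model = un.build_unet(un.UNetSpec(widths=config.unet.widths), seed=config.unet.seed)
    tcfg = un.TrainConfig(
        lr=config.train.lr,
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        split=config.train.split,
        seed=seed,
        stop_train_loss=config.train.stop_train_loss,
        stop_train_iou=config.train.stop_train_iou,
    )
    hist = un.train(model, imgs[tr], labels[tr], imgs[va], labels[va], tcfg)
    un.save_checkpoint(out / "model.ckpt.npz", model, tcfg, seed)
    (out / "history.json").write_text(
        json.dumps(
            {
                "train_loss": hist.train_loss,
                "val_loss": hist.val_loss,
                "train_acc": hist.train_acc,
                "val_acc": hist.val_acc,
                "best_epoch": hist.best_epoch,
            },
            indent=1,
        )
    )
    _stage("train", t0, epochs=hist.n_epochs, best_epoch=hist.best_epoch)

    t0 = time.perf_counter()
    dl_mask = un.predict(model, test_res.volume)
    write_mask(dl_mask, out / "mask_dl.tif")
    _stage("predict", t0)

    t0 = time.perf_counter()
    summary = met.iou_summary(dl_mask, test_res.mask)
    window = tuple(config.projection.window_um)
    proj_dl = met.project(dl_mask, window)
    proj_conv = met.project(test_res.mask, window)
    report.update(
        {
            "mean_iou": summary.mean_iou,
            "sd_iou": summary.sd_iou,
            "n_bscans": len(summary.per_bscan_iou),
            "area_density_dl_pct": met.area_density(proj_dl),
            "area_density_conv_pct": met.area_density(proj_conv),
            "volume_density_dl_pct": met.volume_density(dl_mask, window),
            "volume_density_conv_pct": met.volume_density(test_res.mask, window),
            "train_final_loss": hist.train_loss[-1],
            "train_final_acc": hist.train_acc[-1],
            "val_final_acc": hist.val_acc[-1],
            "epochs_run": hist.n_epochs,
            "theta_db": train_res.theta_db,
        }
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _stage("metrics", t0, mean_iou=round(summary.mean_iou, 3))
    return report


def run_scaled_study(seed: int = 1, widths: tuple[int, ...] = (8, 16, 32, 64),
                     epochs: int = 100, stop_train_loss: float = 0.05) -> dict:
    """Desk-scale version of the full study, returning measured quantities.

    One clean training phantom (64 B-scans of 128 x 128 after flattening and
    cropping; half are the training group), one held-out phantom, and one
    heterogeneous phantom with a 10 dB superficial layer.  Conventional
    labels are generated for all three; a width-reduced U-Net is trained on
    the clean labels (Adam, Dice loss, early stop once the training loss
    reaches ``stop_train_loss``), then evaluated on the held-out volume
    against the conventional labels and on the heterogeneous volume against
    the geometric truth.

    Returns a dict of scalars (IOUs, loss/accuracy series, false-positive
    fractions) plus the fitted objects for further inspection.
    """
    config = RunConfig(seed=seed)
    cal, train_vol, train_truth, test_vol, test_truth = simulate_inputs(config, seed)
    train_vol = normalize_noise(train_vol)
    test_vol = normalize_noise(test_vol)

    conv_cfg = conv.ConventionalConfig()
    train_res = conv.run_conventional(train_vol, cal, conv_cfg)
    test_res = conv.run_conventional(test_vol, cal, conv_cfg)

    # label quality vs geometric truth on the training phantom
    truth_mask = conv.flatten_and_crop(
        _truth_mask(train_truth, train_vol), train_res.surface, conv_cfg.crop_um
    )
    label_iou = met.iou(train_res.mask.data, truth_mask.data)

    imgs, labels, vmax = training_set_from_result(train_res)
    tr, va, te = un.split_dataset(len(imgs), config.train.split, seed=seed)
    model = un.build_unet(un.UNetSpec(widths=tuple(widths)), seed=config.unet.seed)
    tcfg = un.TrainConfig(epochs=epochs, seed=seed, stop_train_loss=stop_train_loss)
    hist = un.train(model, imgs[tr], labels[tr], imgs[va], labels[va], tcfg)

    dl_mask = un.predict(model, test_res.volume)
    heldout = met.iou_summary(dl_mask, test_res.mask)

    # heterogeneous phantom: 75 um superficial layer, 10 dB darker
    p = config.phantom
    layer_spec = _phantom_spec(
        config.model_copy(
            update={"phantom": p.model_copy(update={"layer_thickness_um": 75.0})}
        ),
        seed + 9,
        with_layer=True,
    )
    rng = np.random.default_rng(seed + 20)
    layer_spec = replace(
        layer_spec,
        vessels=ph.sample_vessels(layer_spec, p.n_lymphatic, p.n_vein, rng,
                                  deficit_db=p.vessel_deficit_db),
    )
    layer_vol, layer_truth = ph.make_eye_phantom(layer_spec)
    layer_vol = normalize_noise(layer_vol)
    layer_res = conv.run_conventional(layer_vol, cal, conv_cfg)
    layer_gt = conv.flatten_and_crop(
        _truth_mask(layer_truth, layer_vol), layer_res.surface, conv_cfg.crop_um
    )
    layer_px = int(round(75.0 / layer_vol.physical_pitch_um))
    fp_conv = layer_res.mask.data & ~layer_gt.data
    sup_conv = float(fp_conv[:, :, :layer_px].mean())
    deep_conv = float(fp_conv[:, :, layer_px:].mean())
    dl_layer = un.predict(model, layer_res.volume)
    fp_dl = dl_layer.data & ~layer_gt.data
    sup_dl = float(fp_dl[:, :, :layer_px].mean())

    return {
        "label_iou_vs_truth": label_iou,
        "train_loss": hist.train_loss,
        "val_loss": hist.val_loss,
        "train_acc": hist.train_acc,
        "val_acc": hist.val_acc,
        "epochs_run": hist.n_epochs,
        "best_epoch": hist.best_epoch,
        "heldout_mean_iou": heldout.mean_iou,
        "heldout_sd_iou": heldout.sd_iou,
        "superficial_fp_conv": sup_conv,
        "deep_fp_conv": deep_conv,
        "superficial_fp_dl": sup_dl,
        "model": model,
        "history": hist,
        "train_res": train_res,
        "test_res": test_res,
        "layer_res": layer_res,
    }


def _truth_mask(truth: ph.GroundTruth, vol: OCTVolume):
    from .volume import VesselMask

    return VesselMask(truth.mask, provenance="ground_truth",
                      physical_pitch_um=vol.physical_pitch_um)
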