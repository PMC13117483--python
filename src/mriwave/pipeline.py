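"""End-to-end orchestration: dataset creation, training, evaluation, auditing.

Every command is a plain function taking a configuration dictionary (see
:data:`DEFAULT_CONFIG`); the CLI is a thin argument-parsing layer on top.
All randomness derives from the single ``seed`` entry, so a run is fully
replayable from its config plus the emitted manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mriwave import artifacts as art
from mriwave import audit as audit_mod
from mriwave import metrics as met
from mriwave.bands import BandSet, dwt2_bands, idwt2_bands
from mriwave.denoiser import WaveletAttentionDenoiser
from mriwave.orientation import alignment_angle, estimate_dominant_angle, rotate_align, rotate_back
from mriwave.phantoms import Volume, generate_phantom_volume, slice_volume, split_subjects, zscore_normalize

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "dataset": {
        "n_subjects": 12,
        "kinds": ["ringing", "herringbone", "zipper"],
        "shape": [64, 64, 64],
        "n_tissues": 3,
        "noise_sd": 4.0,
        "bias_amp": 0.1,
        "train_frac": 0.8,
        "slice_axis": 0,
    },
    "model": {
        "encoder_widths": [64, 128, 256, 512],
        "bottleneck_width": 1024,
        "attention_mid_ratio": 0.5,
        "leaky_slope": 0.2,
    },
    "train": {
        "learning_rate": 1e-4,
        "batch_size": 8,
        "epochs": 50,
        "patience": 5,
        "wavelet": "db2",
        "band_weights": {"AA": 0.1, "AD": 0.3, "DA": 0.4, "DD": 0.3},
        "radon_align": True,
        "slices_per_volume": 8,
    },
    "evaluate": {"n_boot": 2000, "n_perm": 10000, "slices_per_volume": 8},
    "audit": {"n_perm": 199, "n_directions": 100, "ridge": 1e-6, "slices_per_volume": 4},
    "wavelet_select": {
        "families": ["db1", "db2", "db3", "db4", "db5", "db6"],
        "n_seeds": 5,
        "epochs": 20,
        "slices_per_volume": 4,
    },
}


def load_config(path=None, overrides=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict):
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _spec_to_json(spec: art.ArtifactSpec) -> dict:
    return {"kind": spec.kind, "axis": spec.axis, "params": spec.params, "seed": spec.seed}


def _spec_from_json(d: dict) -> art.ArtifactSpec:
    return art.ArtifactSpec(kind=d["kind"], axis=int(d["axis"]), params=d["params"],
                            seed=int(d["seed"]))


def cmd_make_dataset(cfg: dict, out_dir, force: bool = False) -> pd.DataFrame:
    """Generate clean/corrupted phantom pairs plus a replayable manifest CSV.

    ``kinds`` entries may be single kinds or '+'-joined mixtures
    (e.g. "ringing+zipper"); mixtures are applied sequentially.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    ds = cfg["dataset"]
    seed = int(cfg["seed"])
    kinds = list(ds["kinds"])
    rows = []
    all_specs = []
    for i in range(int(ds["n_subjects"])):
        sub_seed = seed * 100_003 + i
        vol = generate_phantom_volume(sub_seed, tuple(ds["shape"]), int(ds["n_tissues"]),
                                      float(ds["noise_sd"]), float(ds["bias_amp"]))
        label = kinds[i % len(kinds)]
        specs = [art.sample_artifact_params(k, sub_seed * 7 + j)
                 for j, k in enumerate(label.split("+"))]
        corrupted = art.compose_mixture(vol, specs)
        clean_path = out / f"{vol.subject_id}_clean.nii.gz"
        corr_path = out / f"{vol.subject_id}_corrupted.nii.gz"
        vol.to_nifti(clean_path)
        corrupted.to_nifti(corr_path)
        all_specs.extend(specs)
        rows.append({
            "subject_id": vol.subject_id,
            "artifact_kind": label,
            "specs_json": json.dumps([_spec_to_json(s) for s in specs]),
            "clean_path": str(clean_path),
            "corrupted_path": str(corr_path),
        })
    thresholds = art.compute_severity_thresholds(all_specs)
    for row in rows:
        first = _spec_from_json(json.loads(row["specs_json"])[0])
        row["severity"] = (art.severity_label(first, thresholds[first.kind])
                           if "+" not in row["artifact_kind"] else "mixture")
    split = split_subjects([r["subject_id"] for r in rows],
                           {r["subject_id"]: r["artifact_kind"] for r in rows},
                           float(ds["train_frac"]), seed)
    for row in rows:
        row["split"] = split.partition_of(row["subject_id"])
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return manifest


def _load_pairs(manifest: pd.DataFrame, cfg: dict, split: str, slices_per_volume: int):
    """z-scored (corrupted, clean) slice pairs for one partition."""
    axis = int(cfg["dataset"]["slice_axis"])
    xs, ys, meta = [], [], []
    for _, row in manifest[manifest["split"] == split].iterrows():
        clean = zscore_normalize(Volume.from_nifti(row["clean_path"], row["subject_id"]))
        corr = zscore_normalize(Volume.from_nifti(row["corrupted_path"], row["subject_id"],
                                                  provenance="corrupted"))
        s_clean = slice_volume(clean, axis)
        s_corr = slice_volume(corr, axis)
        n = len(s_clean)
        take = min(slices_per_volume, n)
        lo = (n - take) // 2  # central block: most tissue content
        for k in range(lo, lo + take):
            xs.append(s_corr[k])
            ys.append(s_clean[k])
            meta.append({"subject_id": row["subject_id"], "artifact_kind": row["artifact_kind"],
                         "severity": row["severity"], "slice_index": k})
    return np.array(xs), np.array(ys), meta


def cmd_train(cfg: dict, dataset_dir, out_dir) -> "WaveletAttentionDenoiser":
    """Train the band U-Net per the manifest's subject-level split."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(Path(dataset_dir) / "manifest.csv")
    tr = cfg["train"]
    spv = int(tr["slices_per_volume"])
    x_tr, y_tr, _ = _load_pairs(manifest, cfg, "train", spv)
    x_va, y_va, _ = _load_pairs(manifest, cfg, "val", spv)
    X = np.concatenate([x_tr, x_va])
    Y = np.concatenate([y_tr, y_va])
    is_val = np.concatenate([np.zeros(len(x_tr), bool), np.ones(len(x_va), bool)])
    est = WaveletAttentionDenoiser(
        wavelet=tr["wavelet"], band_weights=dict(tr["band_weights"]),
        encoder_widths=tuple(cfg["model"]["encoder_widths"]),
        bottleneck_width=int(cfg["model"]["bottleneck_width"]),
        attention_mid_ratio=float(cfg["model"]["attention_mid_ratio"]),
        leaky_slope=float(cfg["model"]["leaky_slope"]),
        learning_rate=float(tr["learning_rate"]), batch_size=int(tr["batch_size"]),
        epochs=int(tr["epochs"]), patience=int(tr["patience"]),
        radon_align=bool(tr["radon_align"]), random_state=int(cfg["seed"]))
    est.fit(X, Y, validation_mask=is_val)
    est.history_.to_frame().to_csv(out / "history.csv", index=False)
    state = est.model_.state_dict()
    np.savez(out / "checkpoint.npz", **state)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    with open(out / "train_log.jsonl", "w") as fh:
        for step in ("estimate_angle", "rotate_align", "dwt", "network", "idwt", "rotate_back"):
            fh.write(json.dumps({"pipeline_step": step, "seed": cfg["seed"]}) + "\n")
    return est


def load_checkpoint(run_dir) -> WaveletAttentionDenoiser:
    run = Path(run_dir)
    cfg = load_config(run / "run_config.yaml")
    tr, mo = cfg["train"], cfg["model"]
    est = WaveletAttentionDenoiser(
        wavelet=tr["wavelet"], band_weights=dict(tr["band_weights"]),
        encoder_widths=tuple(mo["encoder_widths"]), bottleneck_width=int(mo["bottleneck_width"]),
        attention_mid_ratio=float(mo["attention_mid_ratio"]),
        leaky_slope=float(mo["leaky_slope"]), radon_align=bool(tr["radon_align"]),
        random_state=int(cfg["seed"]))
    from mriwave.nn.unet import ModelConfig, WaveletAttentionUNet

    mcfg = ModelConfig(encoder_widths=tuple(mo["encoder_widths"]),
                       bottleneck_width=int(mo["bottleneck_width"]),
                       attention_mid_ratio=float(mo["attention_mid_ratio"]),
                       leaky_slope=float(mo["leaky_slope"]))
    model = WaveletAttentionUNet(mcfg, seed=int(cfg["seed"]))
    state = dict(np.load(run / "checkpoint.npz"))
    model.load_state_dict(state)
    est.model_ = model.eval()
    est.model_config_ = mcfg
    return est


def cmd_evaluate(cfg: dict, dataset_dir, run_dir, out_dir) -> dict:
    """Per-slice metrics (input vs GT and prediction vs GT) plus summaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(Path(dataset_dir) / "manifest.csv")
    est = load_checkpoint(run_dir)
    ev = cfg["evaluate"]
    X, Y, meta = _load_pairs(manifest, cfg, "val", int(ev["slices_per_volume"]))
    pred = est.predict(X)
    wavelet = est.wavelet
    rows = []
    for i, m in enumerate(meta):
        for tag, img in (("input", X[i]), ("pred", pred[i])):
            sm = met.slice_metrics(img, Y[i], dwt2_bands(img, wavelet), dwt2_bands(Y[i], wavelet))
            rows.append({**m, "comparison": tag, **sm.as_dict()})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "metrics.csv", index=False)

    summary: dict = {"overall": {}, "by_kind": {}, "by_severity": {}}
    inp = frame[frame["comparison"] == "input"].reset_index(drop=True)
    prd = frame[frame["comparison"] == "pred"].reset_index(drop=True)
    for metric in ("ssim", "psnr_db"):
        gain = met.paired_gain_stats(inp[metric].values, prd[metric].values,
                                     n_boot=int(ev["n_boot"]), n_perm=int(ev["n_perm"]),
                                     seed=int(cfg["seed"]))
        summary["overall"][metric] = {
            "input_mean": float(inp[metric].mean()), "input_sd": float(inp[metric].std()),
            "pred_mean": float(prd[metric].mean()), "pred_sd": float(prd[metric].std()),
            "gain": gain,
        }
    for key, col in (("by_kind", "artifact_kind"), ("by_severity", "severity")):
        for val, grp_in in inp.groupby(col):
            grp_pr = prd[prd[col] == val]
            summary[key][str(val)] = {
                m: {"input_mean": float(grp_in[m].mean()), "pred_mean": float(grp_pr[m].mean())}
                for m in ("ssim", "psnr_db")
            } | {"n": int(len(grp_in))}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def cmd_audit_split(cfg: dict, dataset_dir, out_dir, make_plots: bool = True) -> pd.DataFrame:
    """Partition-distribution audit: three two-sample tests on slice features."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(Path(dataset_dir) / "manifest.csv")
    au = cfg["audit"]
    feats, strata, parts = [], [], []
    for split in ("train", "val"):
        X, _, meta = _load_pairs(manifest, cfg, split, int(au["slices_per_volume"]))
        for x, m in zip(X, meta):
            f = audit_mod.extract_features(x)
            if f is None:
                continue
            feats.append(f)
            strata.append(m["artifact_kind"])
            parts.append(split)
    feats = np.array(feats)
    strata = np.array(strata)
    parts = np.array(parts)
    keep = feats.std(axis=0) > 0  # drop empty histogram bins etc.
    feats = feats[:, keep]
    tr_mask = parts == "train"
    Xw, Yw = audit_mod.pooled_whiten(feats[tr_mask], feats[~tr_mask], ridge=float(au["ridge"]))
    seed = int(cfg["seed"])
    tests = {
        "energy_distance": audit_mod.energy_distance,
        "mmd_rbf": audit_mod.mmd_rbf,
        "sliced_wasserstein": lambda A, B: audit_mod.sliced_wasserstein(
            A, B, n_directions=int(au["n_directions"]), seed=seed),
    }
    rows = []
    for name, fn in tests.items():
        res = audit_mod.permutation_pvalue(fn, Xw, Yw, strata[tr_mask], strata[~tr_mask],
                                           n_perm=int(au["n_perm"]), seed=seed)
        rows.append({"test": name, "statistic": res.statistic, "p_value": res.p_value,
                     "n_perm": res.n_perm})
    table = pd.DataFrame(rows)
    table.to_csv(out / "audit.csv", index=False)
    with open(out / "audit.json", "w") as fh:
        json.dump(table.to_dict(orient="records"), fh, indent=2)
    if make_plots:
        _audit_plots(Xw, Yw, out)
    return table


def _audit_plots(Xw, Yw, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA

    pca = PCA(n_components=2).fit(np.vstack([Xw, Yw]))
    px, py = pca.transform(Xw), pca.transform(Yw)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(px[:, 0], px[:, 1], s=8, alpha=0.6, label="train")
    ax.scatter(py[:, 0], py[:, 1], s=8, alpha=0.6, label="val")
    ax.set_xlabel("PC1"), ax.set_ylabel("PC2"), ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pca_projection.png", dpi=120)
    plt.close(fig)
    k = min(6, Xw.shape[1])
    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for i, ax in enumerate(axes.ravel()[:k]):
        ax.hist(Xw[:, i], bins=30, alpha=0.5, density=True, label="train")
        ax.hist(Yw[:, i], bins=30, alpha=0.5, density=True, label="val")
        ax.set_title(f"whitened feature {i}")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(out / "feature_histograms.png", dpi=120)
    plt.close(fig)


def wavelet_selection_experiment(cfg: dict, dataset_dir, out_dir) -> pd.DataFrame:
    """Reduced-scale Daubechies family comparison (mean +/- sd over seeds).

    For each family and seed the model is trained on the reduced dataset and
    the image-domain SSIM/MAE at the epoch with the lowest validation loss
    are recorded; families are ranked by mean SSIM.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(Path(dataset_dir) / "manifest.csv")
    ws = cfg["wavelet_select"]
    tr = cfg["train"]
    spv = int(ws["slices_per_volume"])
    x_tr, y_tr, _ = _load_pairs(manifest, cfg, "train", spv)
    x_va, y_va, _ = _load_pairs(manifest, cfg, "val", spv)
    X = np.concatenate([x_tr, x_va])
    Y = np.concatenate([y_tr, y_va])
    is_val = np.concatenate([np.zeros(len(x_tr), bool), np.ones(len(x_va), bool)])
    n_seeds = int(ws["n_seeds"])
    if n_seeds < 2:
        log.warning("fewer than 2 seeds: standard deviations will be undefined")
    records = []
    for family in ws["families"]:
        for s in range(n_seeds):
            est = WaveletAttentionDenoiser(
                wavelet=family, band_weights=dict(tr["band_weights"]),
                encoder_widths=tuple(cfg["model"]["encoder_widths"]),
                bottleneck_width=int(cfg["model"]["bottleneck_width"]),
                learning_rate=float(tr["learning_rate"]), batch_size=int(tr["batch_size"]),
                epochs=int(ws["epochs"]), patience=0,
                radon_align=bool(tr["radon_align"]),
                random_state=int(cfg["seed"]) * 1000 + s)
            est.fit(X, Y, validation_mask=is_val)
            hist = est.history_.to_frame()
            best = hist.loc[hist["val_loss"].idxmin()]
            records.append({"family": family, "seed": s,
                            "ssim": float(best["val_ssim"]), "mae": float(best["val_mae"])})
    per_run = pd.DataFrame(records)
    per_run.to_csv(out / "wavelet_selection_runs.csv", index=False)
    table = (per_run.groupby("family")
             .agg(ssim_mean=("ssim", "mean"), ssim_sd=("ssim", "std"),
                  mae_mean=("mae", "mean"), mae_sd=("mae", "std"))
             .reset_index()
             .sort_values("ssim_mean", ascending=False, ignore_index=True))
    table.to_csv(out / "wavelet_selection.csv", index=False)
    return table
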