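"""End-to-end orchestration: dataset -> per-subject metrics -> Task-PLS.

Feature extractors reduce each (subject, condition) cell's segments to one
metric vector (mean over segments), producing the observation-by-element
blocks that mean-centered Task-PLS consumes. ``run_analysis`` ties dataset
synthesis/ingestion, metric extraction and per-metric PLS into one seeded,
manifest-logged run; ``run_simulation_study`` does the same for the
oscillator parameter sweep and state clustering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, oscillator, phase, synth, univariate
from .pls import MeanCenteredTaskPLS
from .synth import StudyDataset, SynthSpec

logger = logging.getLogger(__name__)

EEG_WINDOW_SAMPLES = 251
EEG_WINDOW_STEP = 1


def segment_jl_features(
    seg,
    cfg: phase.WaveletConfig,
    window_samples: int = EEG_WINDOW_SAMPLES,
    step_samples: int = EEG_WINDOW_STEP,
    taus: np.ndarray | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-segment jump-length grid and PS-norm stats, as flat labelled series."""
    tf = phase.morlet_phase(seg, cfg)
    ss = phase.sliding_sync(tf, window_samples, step_samples)
    psd = dynamics.psd_matrix(ss)
    if taus is None:
        taus = dynamics.snapped_tau_grid(psd.step_s)
    grid = dynamics.jl_grid(psd, taus=taus)
    jl = {}
    for stat, arr in (("mu_jl", grid.mean), ("sigma_jl", grid.sd),
                      ("k_jl", grid.kurtosis)):
        for ti, tau in enumerate(grid.taus):
            for fi, f in enumerate(grid.freqs):
                jl[f"{stat}|tau={tau:.3f}|f={f:g}"] = arr[ti, fi]
    norm = phase.ps_norm_series(ss)
    mu, sd = phase.ps_norm_stats(norm)
    ps = {}
    for fi, f in enumerate(ss.freqs):
        ps[f"mu_ps|f={f:g}"] = mu[fi]
        ps[f"sigma_ps|f={f:g}"] = sd[fi]
    return pd.Series(jl), pd.Series(ps)


def dataset_features(
    dataset: StudyDataset,
    freqs=None,
    window_samples: int = EEG_WINDOW_SAMPLES,
    step_samples: int = EEG_WINDOW_STEP,
    taus: np.ndarray | None = None,
    include_univariate: bool = False,
    entropy_scales=range(1, 26),
) -> dict[str, pd.DataFrame]:
    """Per-(subject, condition) metric blocks, averaged over segments.

    Returns a mapping metric-name -> DataFrame whose index is (subject,
    group, condition) and whose columns are metric elements, ready for
    :class:`~eegdyn.pls.MeanCenteredTaskPLS`.
    """
    if freqs is None:
        freqs = phase.DEFAULT_FREQS
    cfg = phase.WaveletConfig(freqs=tuple(freqs))
    jl_rows, ps_rows, uni_rows = {}, {}, {}
    for (subject, condition), segs in dataset.segments.items():
        group = segs[0].group_label
        jl_acc, ps_acc, uni_acc = [], [], []
        for seg in segs:
            jl, ps = segment_jl_features(seg, cfg, window_samples,
                                         step_samples, taus)
            jl_acc.append(jl)
            ps_acc.append(ps)
            if include_univariate:
                uni_acc.append(_segment_univariate(seg, entropy_scales))
        key = (subject, group, condition)
        jl_rows[key] = pd.concat(jl_acc, axis=1).mean(axis=1)
        ps_rows[key] = pd.concat(ps_acc, axis=1).mean(axis=1)
        if include_univariate:
            uni_rows[key] = pd.concat(uni_acc, axis=1).mean(axis=1)
    out = {
        "jl": pd.DataFrame(jl_rows).T,
        "ps_norm": pd.DataFrame(ps_rows).T,
    }
    if include_univariate:
        out["univariate"] = pd.DataFrame(uni_rows).T
    for df in out.values():
        df.index = pd.MultiIndex.from_tuples(df.index,
                                             names=["subject", "group",
                                                    "condition"])
    return out


def _segment_univariate(seg, scales) -> pd.Series:
    spec = univariate.power_spectrum(seg)
    sig = univariate.multiscale_std(seg, scales)
    mse = univariate.multiscale_entropy(
        seg, scales, univariate.EntropyParams(r_mode="scale1_sd"))
    msen = univariate.multiscale_entropy(
        seg, scales, univariate.EntropyParams(r_mode="per_scale_sd"))
    vals = {}
    for ch_i, ch in enumerate(seg.channel_labels):
        for fi, f in enumerate(spec.freqs):
            vals[f"P|ch={ch}|f={f:g}"] = spec.power[ch_i, fi]
        for curve, tag in ((sig, "sigma"), (mse, "MSE"), (msen, "MSEn")):
            for si, s in enumerate(curve.scales_s):
                vals[f"{tag}|ch={ch}|scale={s:.3f}"] = curve.values[ch_i, si]
    return pd.Series(vals)


def run_pls(features: pd.DataFrame, n_perm: int = 1000, n_boot: int = 500,
            seed: int | None = None) -> MeanCenteredTaskPLS:
    """Fit mc-Task PLS on a feature block produced by :func:`dataset_features`."""
    idx = features.index.to_frame(index=False)
    y = idx[["group", "condition"]].to_numpy()
    return MeanCenteredTaskPLS(
        n_perm=n_perm, n_boot=n_boot, random_state=seed,
    ).fit(features.to_numpy(), y, subjects=idx["subject"].to_numpy())


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_analysis(config: dict, out_dir: str | Path) -> dict:
    """Synthesize (or load) a cohort, extract metrics, run per-metric PLS.

    ``config`` keys: "synth" (SynthSpec fields), "analysis" (freqs,
    window_samples, step_samples, include_univariate), "pls" (n_perm, n_boot,
    seed). Every random stage must carry an explicit seed. Writes tidy metric
    CSVs, PLS summaries, and a manifest; returns the result bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    _validate_config(config)

    spec = SynthSpec(**config["synth"])
    dataset = synth.gen_study(spec)
    ana = config.get("analysis", {})
    features = dataset_features(
        dataset,
        freqs=ana.get("freqs"),
        window_samples=ana.get("window_samples", EEG_WINDOW_SAMPLES),
        step_samples=ana.get("step_samples", EEG_WINDOW_STEP),
        taus=np.asarray(ana["taus"]) if "taus" in ana else None,
        include_univariate=ana.get("include_univariate", False),
    )
    pls_cfg = config.get("pls", {})
    models = {}
    for name, block in features.items():
        block.to_csv(out_dir / f"features_{name}.csv")
        model = run_pls(block, n_perm=pls_cfg.get("n_perm", 1000),
                        n_boot=pls_cfg.get("n_boot", 500),
                        seed=pls_cfg.get("seed", 0))
        model.summary().to_csv(out_dir / f"pls_{name}_summary.csv", index=False)
        np.savetxt(out_dir / f"pls_{name}_bootstrap_ratios.csv",
                   model.bootstrap_ratios_, delimiter=",")
        models[name] = model
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "elapsed_s": round(time.time() - t0, 2),
        "n_observations": {k: int(v.shape[0]) for k, v in features.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"dataset": dataset, "features": features, "models": models,
            "manifest": manifest}


def _validate_config(config: dict) -> None:
    if "synth" not in config:
        raise ValueError("config must contain a 'synth' block")
    if "seed" not in config["synth"]:
        raise ValueError("synth block must carry an explicit seed")
    if "pls" in config and "seed" not in config["pls"]:
        raise ValueError("pls block must carry an explicit seed")


def run_simulation_study(config: dict, out_dir: str | Path) -> dict:
    """Oscillator sweep + k-medoids clustering of the metastable cell.

    ``config`` keys: "connectome" (path or null for the bundled synthetic
    one), "sweep" (a_grid, K_grid, n_seeds, base_seed), "cluster" (a, K, k,
    seed). Writes the tidy sweep table and cluster outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sweep_cfg = config.get("sweep", {})
    if "base_seed" not in sweep_cfg:
        raise ValueError("sweep block must carry an explicit base_seed")
    W_raw = (oscillator.load_connectome(config["connectome"])
             if config.get("connectome")
             else oscillator.synthetic_connectome())
    W = oscillator.normalize_connectome(W_raw)
    table = oscillator.parameter_sweep(
        W,
        a_grid=sweep_cfg.get("a_grid", oscillator.DEFAULT_A_GRID),
        K_grid=sweep_cfg.get("K_grid", oscillator.DEFAULT_K_GRID),
        n_seeds=sweep_cfg.get("n_seeds", 1),
        base_seed=sweep_cfg["base_seed"],
    )
    table.to_csv(out_dir / "sweep.csv", index=False)
    result = {"sweep": table}
    if "cluster" in config:
        cl = config["cluster"]
        params = oscillator.OscParams(W=W, a=cl.get("a", 0.5),
                                      K=cl.get("K", 2.0), seed=cl["seed"])
        traj = oscillator.simulate(params)
        _, psd = oscillator.sim_sync_pipeline(traj)
        km = oscillator.kmedoids_cluster(psd, k=cl.get("k", 3),
                                         seed=cl["seed"])
        embedding = oscillator.medoid_embedding(psd, km.medoid_indices_)
        np.savetxt(out_dir / "cluster_labels.csv", km.labels_, fmt="%d")
        np.savetxt(out_dir / "embedding.csv", embedding, delimiter=",")
        result.update({"cluster": km, "embedding": embedding, "psd": psd})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"config": config, "config_hash": _config_hash(config)},
                  fh, indent=2, default=str)
    return result
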