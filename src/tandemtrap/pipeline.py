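"""End-to-end orchestration: simulate -> metrics -> null -> posture -> classify.

``run_pipeline`` runs the whole analysis deterministically from a
:class:`RunConfig`, writing metric tables, the null comparison, density
maps, the fitted role classifier, the snapshot classification, and a
machine-readable JSON summary of every headline statistic.  Events may be
simulated or loaded from trajectory tables (reproduction mode for a local
copy of a deposited dataset); no stage touches the network.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import tomllib
from pathlib import Path

import numpy as np

from . import io, kinematics, nullmodel, posture, simulate, stats
from .types import PairEvent

SCHEMA_VERSION = 1

log = logging.getLogger("tandemtrap")


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Unknown keys in a config file are rejected; the resolved config is
    written beside the outputs for auditability.
    """

    seed: int = 1
    outdir: str = "tandemtrap_run"
    # simulation (ignored when tracks/meta paths are given)
    n_natural: int = 20
    n_trapped: int = 20
    duration_s: float = 600.0
    fps_natural: float = 25.0
    fps_trapped: float = 30.0
    # input data (reproduction mode)
    tracks_path: str | None = None
    meta_path: str | None = None
    snapshot_path: str | None = None
    snapshot_f_bl_mm: float = 6.5
    snapshot_m_bl_mm: float = 5.5
    # analysis parameters
    target_fps: float = 1.0
    p_cutoff: float = 0.9
    n_replicates: int = 200
    normalization: str = "mean_bl"
    density_extent_bl: float = 2.0
    density_bin_bl: float = 0.1
    trapped_times_min: tuple[float, ...] = (10.0, 20.0, 30.0)
    make_figures: bool = False

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "trapped_times_min" in raw:
            raw["trapped_times_min"] = tuple(raw["trapped_times_min"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trapped_times_min"] = list(d["trapped_times_min"])
        return d


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def _elapsed(name: str, t0: float) -> None:
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def both_trapped_window(event: PairEvent) -> PairEvent:
    """Frames from trap entry to the first escape (or observation end)."""
    return event.window(event.entry_frame, event.both_trapped_stop())


def _pooled_speeds(events: list[PairEvent]) -> np.ndarray:
    vals = []
    for ev in events:
        for ind in (ev.female, ev.male):
            if ind.n_frames >= 2:
                vals.append(kinematics.speed_bl_s(ind, ev.fps))
    return np.concatenate(vals) if vals else np.empty(0)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(8) % (2**31)

    # ------------------------------------------------------------------ data
    t0 = _stage("events")
    if config.tracks_path and config.meta_path:
        events = io.read_pair_events(config.tracks_path, config.meta_path)
        natural = [e for e in events if e.condition == "natural"]
        trapped = [e for e in events if e.condition == "trapped"]
        params = simulate.SyntheticParams(seed=int(seeds[0]))
        posture_frames = None
    else:
        params = simulate.SyntheticParams(
            seed=int(seeds[0]), duration_s=config.duration_s, fps=config.fps_natural
        )
        natural = simulate.simulate_ensemble(params, "natural", config.n_natural, seed=int(seeds[0]))
        trap_params = dataclasses.replace(params, fps=config.fps_trapped)
        trapped = simulate.simulate_ensemble(trap_params, "trapped", config.n_trapped, seed=int(seeds[1]))
        posture_frames = None
    _elapsed("events", t0)

    # ------------------------------------------------------------- kinematics
    t0 = _stage("kinematics")
    natural_ds = [io.downsample(e, config.target_fps) for e in natural]
    trapped_win = [both_trapped_window(e) for e in trapped]
    trapped_ds = [io.downsample(e, config.target_fps) for e in trapped_win]
    trapped_ds = [e for e in trapped_ds if min(e.female.n_frames, e.male.n_frames) >= 3]

    sp_nat = _pooled_speeds(natural_ds)
    sp_trap = _pooled_speeds(trapped_ds)
    speed_test = stats.rank_sum(sp_nat, sp_trap, exact=False)

    met_nat = [kinematics.pair_metrics(e) for e in natural_ds]
    met_trap = [kinematics.pair_metrics(e) for e in trapped_ds]
    import pandas as pd

    met_all = pd.concat(
        [m.assign(condition="natural", event_id=e.event_id) for m, e in zip(met_nat, natural_ds)]
        + [m.assign(condition="trapped", event_id=e.event_id) for m, e in zip(met_trap, trapped_ds)],
        ignore_index=True,
    )
    met_all.to_csv(outdir / "metrics.csv", index=False)

    dist_nat = np.concatenate([m["distance_bl"].to_numpy() for m in met_nat]) if met_nat else np.empty(0)
    dist_trap = np.concatenate([m["distance_bl"].to_numpy() for m in met_trap])
    dist_test = stats.rank_sum(dist_trap, dist_nat, exact=False) if dist_nat.size else None

    counts = kinematics.trapped_counts(trapped, list(config.trapped_times_min))
    counts.to_csv(outdir / "trapped_counts.csv", index=False)

    dmaps = {}
    for cond, evs in (("natural", natural_ds), ("trapped", trapped_ds)):
        for focal in ("F", "M"):
            try:
                dm = kinematics.density_map(
                    evs, focal, config.density_extent_bl, config.density_bin_bl
                )
            except ValueError:
                continue
            dmaps[f"{cond}_{focal}"] = dm
            np.savetxt(outdir / f"density_{cond}_{focal}.csv", dm.grid, delimiter=",")
            (outdir / f"density_{cond}_{focal}.json").write_text(
                json.dumps(
                    {
                        "focal_sex": dm.focal_sex,
                        "extent_bl": dm.extent_bl,
                        "bin_size_bl": dm.bin_size_bl,
                        "n_obs": dm.n_obs,
                    }
                )
            )
    _elapsed("kinematics", t0)

    # ------------------------------------------------------------------ null
    t0 = _stage("null")
    ens = nullmodel.randomize_pairs(trapped_ds, config.n_replicates, seed=int(seeds[2]))
    hd_trap = np.concatenate([m["heading_diff"].to_numpy() for m in met_trap])
    cmp_dist = nullmodel.compare_real_null(dist_trap, ens, "distance_bl", "ks")
    cmp_head = nullmodel.compare_real_null(hd_trap, ens, "heading_diff", "ks")
    _elapsed("null", t0)

    # --------------------------------------------------------------- posture
    t0 = _stage("posture")
    post_params = dataclasses.replace(params, pos_noise_sd_mm=0.05)
    postures = [
        (e, simulate.skeleton_postures(e, post_params, seed=int(seeds[3]) + i))
        for i, e in enumerate(trapped_ds)
    ]
    tip_rows_a = []
    tip_rows_b = []
    for ev, frames in postures:
        th = posture.tip_head_distances(frames, ev.female.body_length_mm, ev.male.body_length_mm)
        tip_rows_a.append(th["d_fTip_mHead"].to_numpy())
        tip_rows_b.append(th["d_fHead_mTip"].to_numpy())
    tip_a = np.concatenate(tip_rows_a)
    tip_b = np.concatenate(tip_rows_b)
    tip_test = stats.paired_t(tip_b, tip_a)  # positive t when fHead-mTip is larger

    feats = posture.features_from_events(postures, leader_sex="F", normalization=config.normalization)
    model = posture.fit_role_classifier(feats)
    model.to_json(outdir / "role_model.json")
    _elapsed("posture", t0)

    # ------------------------------------------------------------- snapshot
    t0 = _stage("snapshot")
    if config.snapshot_path:
        snap = io.read_snapshot(config.snapshot_path, p_cutoff=0.0)
        snap_label = "snapshot"
    else:
        # synthetic fossil-like stand-in: final settled frame of a male-led
        # trapped pair at the fossil body lengths
        fossil_params = dataclasses.replace(
            params,
            body_length_f_mm=config.snapshot_f_bl_mm,
            body_length_m_mm=config.snapshot_m_bl_mm,
            fps=config.fps_trapped,
            duration_s=min(config.duration_s, 300.0),
            escape_hazard_per_min=0.0,
        )
        ev = simulate.simulate_trapped_pair(fossil_params, leader_sex="M", seed=int(seeds[4]))
        frames = simulate.skeleton_postures(
            ev.window(ev.last_frame, ev.last_frame + 1), fossil_params, seed=int(seeds[5])
        )
        snap = frames[0]
        snap_label = "synthetic_fossil_like"
    norm = 0.5 * (config.snapshot_f_bl_mm + config.snapshot_m_bl_mm)
    snap_feats = [
        posture.relative_head_features(snap, sex, norm, source_id=f"{snap_label}-{sex}")
        for sex in ("F", "M")
    ]
    snap_feats = [f for f in snap_feats if f is not None]
    classified = posture.classify_snapshot(model, snap_feats)
    classified.to_csv(outdir / "snapshot_classification.csv", index=False)
    _elapsed("snapshot", t0)

    # --------------------------------------------------------------- summary
    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "n_events": {"natural": len(natural_ds), "trapped": len(trapped_ds)},
        "speeds_bl_s": {
            "natural_mean": float(np.mean(sp_nat)) if sp_nat.size else None,
            "natural_sd": float(np.std(sp_nat)) if sp_nat.size else None,
            "trapped_mean": float(np.mean(sp_trap)),
            "trapped_sd": float(np.std(sp_trap)),
            "rank_sum_W": speed_test.statistic,
            "rank_sum_p": speed_test.p_value,
        },
        "distance_comparison": {
            "natural_mean_bl": float(np.mean(dist_nat)) if dist_nat.size else None,
            "trapped_mean_bl": float(np.mean(dist_trap)),
            "rank_sum_W": dist_test.statistic if dist_test else None,
            "rank_sum_p": dist_test.p_value if dist_test else None,
        },
        "null_comparison": {
            "n_replicates": ens.n_replicates,
            "distance": dataclasses.asdict(cmp_dist.test) | {
                "real_mean": cmp_dist.real_mean,
                "null_mean": cmp_dist.null_mean,
                "quantile": cmp_dist.real_mean_quantile,
                "p_mc": cmp_dist.p_mc,
            },
            "heading": dataclasses.asdict(cmp_head.test) | {
                "real_mean": cmp_head.real_mean,
                "null_mean": cmp_head.null_mean,
                "quantile": cmp_head.real_mean_quantile,
                "p_mc": cmp_head.p_mc,
            },
        },
        "tip_head": {"paired_t": tip_test.statistic, "p": tip_test.p_value, "n": tip_test.n1},
        "trapped_counts": counts.to_dict(orient="list"),
        "classifier": {
            "n_train": model.n_train,
            "class_balance": model.class_balance,
            "pca_explained_pct": [100 * v for v in model.pca_explained.tolist()],
            "pca_loadings": model.pca_loadings.tolist(),
        },
        "snapshot": {
            "label": snap_label,
            "per_individual": classified.to_dict(orient="records"),
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    if config.make_figures:
        _figures(outdir, dmaps, model, feats, snap_feats)
    return summary


def _figures(outdir: Path, dmaps, model, feats, snap_feats) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, dm in dmaps.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(
            dm.grid.T,
            origin="lower",
            extent=[-dm.extent_bl, dm.extent_bl, -dm.extent_bl, dm.extent_bl],
            cmap="viridis",
        )
        ax.set_xlabel("x (BL)")
        ax.set_ylabel("y (BL)")
        ax.set_title(f"partner density, focal {dm.focal_sex} ({name})")
        fig.savefig(outdir / f"density_{name}.png", dpi=120)
        plt.close(fig)

    X = feats[["d_head_head", "d_head_pronotum", "d_head_abdomen"]].to_numpy()
    scores = model.pca_scores(X)
    fig, ax = plt.subplots(figsize=(5, 4))
    for role, color in (("leader", "tab:red"), ("follower", "tab:blue")):
        m = (feats["role"] == role).to_numpy()
        ax.scatter(scores[m, 0], scores[m, 1], s=4, alpha=0.3, color=color, label=role)
    for f in snap_feats:
        s = model.pca_scores(f.vector())[0]
        ax.scatter(s[0], s[1], marker="*", s=150, color="k")
        ax.annotate(f.source_id, (s[0], s[1]))
    ax.set_xlabel(f"PC1 ({100 * model.pca_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * model.pca_explained[1]:.1f}%)")
    ax.legend()
    fig.savefig(outdir / "pca_roles.png", dpi=120)
    plt.close(fig)


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


__all__ = ["RunConfig", "run_pipeline", "both_trapped_window", "setup_logging", "SCHEMA_VERSION"]
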