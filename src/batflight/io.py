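"""Session readers/writers, pipeline configuration and orchestration.

A session directory holds plain-text tables (trajectory.csv, accel.csv,
keypoints.csv, spikes.csv) plus meta.json; the synthetic generator adds
ground_truth.json.  ``run_pipeline`` executes the analysis stages in
dependency order on a session, writing per-stage CSV/JSON outputs whose
content is fully determined by the seed (no timestamps), so identical
configurations reproduce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import kinematics as fk
from . import recruitment as rc
from . import unitstats as us
from . import wingbeats as wbm
from .core import SessionData
from .dimensionality import (build_group_mean_matrix, dpca_decompose,
                             gpfa_dimensionality, pca_dimensionality,
                             participation_ratio_split)
from .encoding import build_feature_matrix, fit_population
from .synthetic import FEATURE_NAMES

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    speed_threshold: float = 1.0        # m/s, flight segmentation
    min_flight_duration: float = 1.0    # s
    cluster_cutoff: float = 0.5         # m RMS, path clustering
    band_low: float = 4.0               # Hz, wingbeat band-pass
    band_high: float = 14.0
    n_shuffles: int = 1000              # permutation iterations; the
    #                                   # modulation test needs >= ~1/(q/m)
    #                                   # shuffles for BH to have power
    modulation_q: float = 0.01
    phase_q: float = 0.05
    min_spikes_phase: int = 20
    decode_folds: int = 5
    decode_shuffle_iters: int = 20
    glm_folds: int = 5
    glm_alphas: int = 8                 # elastic-net penalty grid size
    elastic_net_l1_wt: float = 0.5
    reliability_threshold: float = 0.3
    popdim_stages: tuple[str, ...] = ("pca", "dpca", "gpfa")
    gpfa_dim_grid: tuple[int, ...] = (2, 4, 6)
    gpfa_bin_ms: float = 20.0
    gpfa_em_iters: int = 15
    stages: tuple[str, ...] = ("kinematics", "wingbeats", "unitstats",
                               "decode", "glm", "popdim")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = dict(d, stages=tuple(d["stages"]))
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def read_session(session_dir: str) -> SessionData:
    """Read and validate a session directory.

    Errors name the offending file/row; a missing keypoints.csv disables
    keypoint analyses (logged); a missing accel.csv disables the wingbeat
    stage downstream.
    """
    def path(name):
        return os.path.join(session_dir, name)

    with open(path("meta.json")) as fh:
        meta = json.load(fh)
    traj = pd.read_csv(path("trajectory.csv"))
    t = traj["t"].to_numpy()
    pos = traj[["x", "y", "z"]].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"trajectory.csv: non-monotone timestamps at row "
                         f"{int(np.argmax(dt <= 0)) + 1}")
    rate = 1.0 / np.median(dt)
    if "sample_rate_hz" in meta and \
            abs(rate - meta["sample_rate_hz"]) > 0.01 * meta["sample_rate_hz"]:
        raise ValueError("sampling rate inconsistent with meta.json")

    accel = None
    if os.path.exists(path("accel.csv")):
        adf = pd.read_csv(path("accel.csv"))
        if len(adf) != len(t):
            raise ValueError("accel.csv length mismatch with trajectory.csv")
        accel = adf[["ax", "ay", "az"]].to_numpy()
    else:
        log.warning("accel.csv missing: wingbeat stage unavailable")
        accel = np.full((len(t), 3), np.nan)

    keypoints = None
    kp_names = meta.get("keypoint_names", [])
    if os.path.exists(path("keypoints.csv")):
        kdf = pd.read_csv(path("keypoints.csv"))
        K = int(kdf["keypoint_id"].max()) + 1
        if len(kdf) != len(t) * K:
            raise ValueError("keypoints.csv incomplete grid")
        keypoints = (kdf[["x", "y", "z"]].to_numpy()
                     .reshape(len(t), K, 3))
    else:
        log.warning("keypoints.csv missing: keypoint analyses unavailable")

    sdf = pd.read_csv(path("spikes.csv"))
    spikes: dict[int, np.ndarray] = {}
    if len(sdf):
        if sdf["t"].isna().any():
            raise ValueError(
                f"spikes.csv: missing time at row "
                f"{int(sdf['t'].isna().idxmax()) + 1}")
        for uid, grp in sdf.groupby("unit_id"):
            st = np.sort(grp["t"].to_numpy())
            spikes[int(uid)] = st
    for uid in range(int(meta.get("n_units", len(spikes)))):
        spikes.setdefault(uid, np.array([]))

    session = SessionData(t=t, pos=pos, accel=accel, spikes=spikes,
                          sample_rate=float(meta.get("sample_rate_hz", rate)),
                          keypoints=keypoints, keypoint_names=kp_names,
                          keypoint_frame=meta.get("keypoint_frame", "body"),
                          meta=meta)
    session.validate()
    return session


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return round(f, 10) if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(payload: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(session: SessionData, cfg: PipelineConfig,
                 out_dir: str) -> dict:
    """Run the analysis stages in dependency order; serialize every output.

    Stage failures produce a partial bundle with a failure manifest.
    Returns the summary report (also written to report.json).
    """
    os.makedirs(out_dir, exist_ok=True)
    report: dict = dict(config=cfg.to_dict(), stages={}, failures={})
    ctx: dict = {}

    def stage_enabled(name):
        return name in cfg.stages

    def record_failure(name, err):
        log.exception("stage %s failed", name)
        report["failures"][name] = repr(err)

    # --- flights & paths (always needed) --------------------------------
    flights_list = fk.segment_flights(session.t, session.pos,
                                      session.sample_rate,
                                      cfg.speed_threshold,
                                      cfg.min_flight_duration)
    fk.cluster_paths(flights_list, cfg.cluster_cutoff)
    flights = pd.DataFrame([dict(flight_id=f.flight_id, start=f.start,
                                 end=f.end, path=f.path_label)
                            for f in flights_list])
    flights.to_csv(os.path.join(out_dir, "flights.csv"), index=False)
    ctx["flights"] = flights
    report["stages"]["segmentation"] = dict(
        n_flights=len(flights), n_paths=int((flights["path"] >= 0).sum()
                                            and flights["path"].max() + 1))

    if stage_enabled("kinematics"):
        try:
            per_path = {}
            for path, fls in flights[flights["path"] >= 0].groupby("path"):
                if len(fls) < 2:
                    continue
                traces = [fk.flight_feature_traces(
                    session, flights_list[int(i)]) for i in fls["flight_id"]]
                per_path[int(path)] = fk.path_reproducibility(traces)
            all_corr = np.concatenate(list(per_path.values())) \
                if per_path else np.array([])
            kin_rows = []
            for f in flights_list:
                sel = (session.t >= f.start) & (session.t <= f.end)
                k = fk.derive_kinematics(session.t[sel], session.pos[sel],
                                         session.sample_rate)
                kin_rows.append(pd.DataFrame(dict(
                    flight_id=f.flight_id, t=k.t, speed=k.speed,
                    g_force=k.g_force, angular_velocity=k.angular_velocity,
                    flight_path_angle=k.flight_path_angle)))
            pd.concat(kin_rows).to_csv(
                os.path.join(out_dir, "kinematics.csv"), index=False,
                float_format="%.6g")
            report["stages"]["kinematics"] = dict(
                reproducibility_median=float(np.median(all_corr))
                if len(all_corr) else None,
                reproducibility_iqr=float(np.subtract(
                    *np.percentile(all_corr, [75, 25])))
                if len(all_corr) else None,
                n_correlations=len(all_corr))
        except Exception as err:
            record_failure("kinematics", err)

    wb_table = None
    theta = None
    if stage_enabled("wingbeats"):
        try:
            wb_table, theta = wbm.detect_wingbeats(
                session.t, session.accel[:, 2], session.sample_rate,
                flights, (cfg.band_low, cfg.band_high), pos=session.pos)
            stats = wbm.period_statistics(wb_table)
            wb_table = wb_table.merge(flights[["flight_id", "path"]],
                                      on="flight_id")
            vectors = _adaptation_vectors(session, wb_table)
            if vectors is not None:
                vectors.to_csv(os.path.join(out_dir, "adaptation.csv"),
                               index=False)
            # group wingbeats per path by kinematic similarity (falls back
            # to ordinal labels without keypoints)
            wb_table["group"] = wb_table["ordinal"]
            if vectors is not None:
                for path, sub in wb_table.groupby("path"):
                    if sub["flight_id"].nunique() < 2:
                        continue
                    v = vectors[vectors["wingbeat_id"]
                                .isin(sub["wingbeat_id"])]
                    labels, score = wbm.group_wingbeats(sub, v,
                                                        seed=cfg.seed)
                    wb_table.loc[sub.index, "group"] = labels
            wb_table.to_csv(os.path.join(out_dir, "wingbeats.csv"),
                            index=False)
            ctx.update(wb_table=wb_table, theta=theta, vectors=vectors)
            report["stages"]["wingbeats"] = dict(
                n_wingbeats=len(wb_table), **stats)
        except Exception as err:
            record_failure("wingbeats", err)

    if stage_enabled("unitstats") and wb_table is not None:
        try:
            ustats = us.unit_statistics(session.spikes, flights, wb_table,
                                        n_shuffles=cfg.n_shuffles,
                                        q=cfg.modulation_q, seed=cfg.seed)
            ustats.to_csv(os.path.join(out_dir, "unit_stats.csv"),
                          index=False)
            ph = us.phase_locking_table(session.spikes, session.t, theta,
                                        flights, n_shuffles=cfg.n_shuffles,
                                        q=cfg.phase_q,
                                        min_spikes=cfg.min_spikes_phase,
                                        seed=cfg.seed)
            ph.to_csv(os.path.join(out_dir, "phase_pairs.csv"), index=False)
            tested = ph[ph["tested"]]
            report["stages"]["unitstats"] = dict(
                frac_modulated=float(ustats["modulated"].mean()),
                median_silent_fraction=float(
                    ustats["silent_wingbeat_fraction"].median()),
                frac_phase_locked_pairs=float(tested["sig"].mean())
                if len(tested) else None)
            ctx["phase_pairs"] = ph
        except Exception as err:
            record_failure("unitstats", err)

    if stage_enabled("decode") and wb_table is not None:
        try:
            out = {}
            for path, sub in wb_table.groupby("path"):
                if sub["flight_id"].nunique() < cfg.decode_folds:
                    continue
                bc = rc.build_barcodes(session.spikes, sub)
                X = bc[[c for c in bc.columns if c.startswith("u")]] \
                    .to_numpy(float)
                conf, acc, _ = rc.decode_wingbeat_group(
                    X, sub["group"].to_numpy(), cfg.decode_folds,
                    seed=cfg.seed)
                null = rc.shuffle_null(X, sub["group"].to_numpy(),
                                       cfg.decode_shuffle_iters,
                                       cfg.decode_folds, seed=cfg.seed)
                out[str(int(path))] = dict(
                    accuracy=acc, band1=rc.band_accuracy(conf, 1),
                    null_mean=float(null["band0"].mean()),
                    confusion=conf.tolist())
            report["stages"]["decode"] = out
            write_report(out, os.path.join(out_dir, "decode_report.json"))
        except Exception as err:
            record_failure("decode", err)

    if stage_enabled("glm") and wb_table is not None:
        try:
            fits_all = []
            for path, sub in wb_table.groupby("path"):
                kin = _per_cycle_kinematics(session, sub)
                X, names = build_feature_matrix(sub, kin)
                counts = {uid: rc.cycle_counts({uid: st}, sub)[:, 0]
                          for uid, st in session.spikes.items()}
                # restrict to units with enough spikes for a stable fit
                counts = {u: c for u, c in counts.items() if c.sum() >= 30}
                fits = fit_population(counts, X, names,
                                      k_folds=cfg.glm_folds,
                                      n_alphas=cfg.glm_alphas,
                                      seed=cfg.seed)
                fits_all.extend(fits)
            rows = [dict(unit_id=f.unit_id,
                         selected=";".join(f.selected),
                         cv_pseudo_r2=f.cv_pseudo_r2,
                         pr_norm=f.weight_pr_normalized)
                    for f in fits_all]
            pd.DataFrame(rows).to_csv(os.path.join(out_dir, "glm_fits.csv"),
                                      index=False)
            report["stages"]["glm"] = dict(
                n_fits=len(rows),
                median_cv_pseudo_r2=float(np.median(
                    [r["cv_pseudo_r2"] for r in rows])) if rows else None)
        except Exception as err:
            record_failure("glm", err)

    if stage_enabled("popdim") and wb_table is not None:
        try:
            out = {}
            for path, sub in wb_table.groupby("path"):
                entry = {}
                if "pca" in cfg.popdim_stages:
                    M, kept, groups = build_group_mean_matrix(
                        session.spikes, sub,
                        reliability_threshold=cfg.reliability_threshold)
                    if len(kept) < 5:
                        continue
                    rep = pca_dimensionality(M)
                    pr_core, pr_ext = participation_ratio_split(rep.spectrum)
                    entry.update(n_units=len(kept), n90=rep.n90,
                                 n90_fraction=rep.n90_fraction,
                                 pr_core=pr_core, pr_extended=pr_ext)
                if "dpca" in cfg.popdim_stages:
                    trials = _trial_tensor(session.spikes, sub)
                    if trials is not None:
                        d = dpca_decompose(trials)
                        entry.update(
                            dpca_ev_specific=d["ev_specific"],
                            dpca_ev_invariant=d["ev_invariant"],
                            dpca_ratio=d["specific_invariant_ratio"])
                if "gpfa" in cfg.popdim_stages:
                    Y = _binned_trials(session.spikes, flights, int(path),
                                       cfg.gpfa_bin_ms)
                    if Y is not None:
                        grid = [g for g in cfg.gpfa_dim_grid
                                if g < Y.shape[1]]
                        res = gpfa_dimensionality(
                            Y, grid, bin_ms=cfg.gpfa_bin_ms,
                            n_iter=cfg.gpfa_em_iters, seed=cfg.seed)
                        entry.update(
                            gpfa_errors={str(k): v for k, v
                                         in res["errors"].items()},
                            gpfa_selected=list(res["selected_dims"]),
                            gpfa_best_dim=res["best_dim"])
                if entry:
                    out[str(int(path))] = entry
            report["stages"]["popdim"] = out
            write_report(out, os.path.join(out_dir, "dim_report.json"))
        except Exception as err:
            record_failure("popdim", err)

    # skipped stages, with reason
    for name in ("kinematics", "wingbeats", "unitstats", "decode", "glm",
                 "popdim"):
        if not stage_enabled(name):
            report["stages"][name] = "skipped: stage toggled off"
        elif name != "kinematics" and wb_table is None \
                and name not in report["stages"]:
            report["stages"][name] = "skipped: wingbeats unavailable"

    write_report(report, os.path.join(out_dir, "report.json"))
    return report


def _adaptation_vectors(session: SessionData, wb_table: pd.DataFrame):
    """Wrist/wingtip envelope + asymmetry vectors; None without keypoints."""
    if session.keypoints is None:
        log.info("no keypoints: adaptation vectors unavailable")
        return None
    envs, asyms = {}, {}
    for base in ("wrist", "wingtip"):
        pair = {}
        for side in ("L", "R"):
            name = f"{base}_{side}"
            if name not in session.keypoint_names:
                continue
            k = session.keypoint_names.index(name)
            env, _ = wbm.extract_envelopes(
                session.t, session.keypoints[:, k, 2], wb_table)
            envs[name] = env
            pair[side] = env
        if len(pair) == 2:
            asyms[base] = wbm.left_right_asymmetry(pair["L"], pair["R"])
    if not envs:
        return None
    return wbm.adaptation_vectors(envs, asyms, wb_table)


def _trial_tensor(spikes, wb_table, n_bins: int = 8, min_flights: int = 4):
    """(flights, units, groups, bins) tensor of warped per-cycle rates.

    Only groups present in every retained flight are used; None when too
    few complete flights exist.
    """
    gcol = "group" if "group" in wb_table.columns else "ordinal"
    flights = sorted(wb_table["flight_id"].unique())
    groups = sorted(wb_table[gcol].unique())
    # keep groups covered by every flight exactly once
    cover = wb_table.groupby([gcol, "flight_id"]).size().unstack(
        fill_value=0)
    groups = [g for g in groups
              if g in cover.index and (cover.loc[g] == 1).all()]
    if len(groups) < 2 or len(flights) < min_flights:
        return None
    unit_ids = sorted(spikes)
    T = np.zeros((len(flights), len(unit_ids), len(groups), n_bins))
    lookup = wb_table.groupby([gcol, "flight_id"]).first()
    for gi, g in enumerate(groups):
        for fi, f in enumerate(flights):
            wb = lookup.loc[(g, f)]
            edges = np.linspace(wb["onset"], wb["offset"], n_bins + 1)
            bw = (wb["offset"] - wb["onset"]) / n_bins
            for ui, uid in enumerate(unit_ids):
                c, _ = np.histogram(spikes[uid], bins=edges)
                T[fi, ui, gi] = c / bw
    return T


def _binned_trials(spikes, flights: pd.DataFrame, path: int, bin_ms: float,
                   min_flights: int = 4):
    """(flights, units, bins) takeoff-aligned count tensor for one path."""
    fls = flights[flights["path"] == path]
    if len(fls) < min_flights:
        return None
    dur = float((fls["end"] - fls["start"]).min())
    n_bins = int(dur / (bin_ms / 1000.0))
    if n_bins < 5:
        return None
    unit_ids = sorted(spikes)
    Y = np.zeros((len(fls), len(unit_ids), n_bins))
    for fi, fl in enumerate(fls.itertuples()):
        edges = fl.start + (bin_ms / 1000.0) * np.arange(n_bins + 1)
        for ui, uid in enumerate(unit_ids):
            c, _ = np.histogram(spikes[uid], bins=edges)
            Y[fi, ui] = c
    return Y


def _per_cycle_kinematics(session: SessionData,
                          table: pd.DataFrame) -> pd.DataFrame:
    """Per-wingbeat means of derived kinematics (for the GLM features)."""
    kin = fk.derive_kinematics(session.t, session.pos, session.sample_rate)
    rows = []
    for wb in table.itertuples():
        sel = (session.t >= wb.onset) & (session.t < wb.offset)
        rows.append(dict(
            wingbeat_id=wb.wingbeat_id,
            speed=float(np.nanmean(kin.speed[sel])),
            g_force=float(np.nanmean(kin.g_force[sel])),
            angular_velocity=float(np.nanmean(kin.angular_velocity[sel])),
            flight_path_angle=float(np.nanmean(kin.flight_path_angle[sel])),
            vx=float(np.nanmean(kin.velocity[sel, 0])),
            vy=float(np.nanmean(kin.velocity[sel, 1])),
            vz=float(np.nanmean(kin.velocity[sel, 2])),
            ax=float(np.nanmean(kin.acceleration[sel, 0])),
            ay=float(np.nanmean(kin.acceleration[sel, 1])),
            az=float(np.nanmean(kin.acceleration[sel, 2])),
            curvature=float(np.nanmean(
                kin.angular_velocity[sel]
                / np.clip(kin.speed[sel], 0.1, None))),
        ))
    return pd.DataFrame(rows)
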