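"""End-to-end analysis pipeline over a cohort of trial bundles.

Stages (each optional, configured by name): ``simulate`` a synthetic
cohort to disk, then ``steadiness`` (per-trial force metrics and the
steadiest-window search), ``firing`` (spike-train filtering, per-unit
statistics, mixed-model group contrasts), ``coherence`` (per-trial and
pooled intermuscular coherence with significance machinery), ``cluster``
(k-shape clustering of ramp-phase EMG envelopes) and ``stats`` (bootstrap
group comparisons).  Every emitted table carries the seed and a hash of
the configuration that produced it; a run log records both plus stage
timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, coherence as coh, firing, force, io as npio, stats
from .synthetic import (CommonDriveSpec, GroupSpec, ProtocolSpec,
                        default_groups, generate_cohort)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

ALL_STAGES = ("simulate", "steadiness", "firing", "coherence", "cluster",
              "stats")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out": "neuropinch_report",
    "stages": list(ALL_STAGES),
    "cohort": {"n_per_group": 2, "n_units": 15},
    "bootstrap_n": 10_000,
    "envelope_decimate": 22,   # cluster on ~100 Hz envelopes
    "plots": False,
}


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _emit(df: pd.DataFrame, path: Path, seed: int, chash: str):
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_hash={chash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute the configured stages; returns the report directory.

    ``config`` is a dict or a YAML file path; missing keys fall back to
    :data:`DEFAULT_CONFIG`.  A stage whose inputs are missing fails fast
    with the stage name in the error.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    chash = _config_hash(cfg)
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    log = {"seed": seed, "config_hash": chash, "stages": {}}

    protocol = ProtocolSpec(**cfg.get("protocol", {}))
    cohort_dir = out / "cohort"

    if "simulate" in stages:
        t0 = time.perf_counter()
        groups = [GroupSpec(name=g.name, n_units=cfg["cohort"].get("n_units", g.n_units),
                            mvc_mean=g.mvc_mean, mvc_sd=g.mvc_sd,
                            drive=g.drive, drive_by_level=g.drive_by_level)
                  for g in default_groups()]
        generate_cohort(groups, protocol, cfg["cohort"]["n_per_group"],
                        seed, cohort_dir)
        log["stages"]["simulate"] = round(time.perf_counter() - t0, 3)

    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        needed = [s for s in stages if s != "simulate"]
        if needed:
            raise FileNotFoundError(
                f"stage '{needed[0]}': no cohort manifest at {manifest_path}; "
                "run the simulate stage or point 'out' at an existing cohort")
        return out
    manifest = json.loads(manifest_path.read_text())

    # ---- load all bundles once -------------------------------------------
    t0 = time.perf_counter()
    records = []   # one dict per trial
    for part in manifest["participants"]:
        for tr in part["trials"]:
            stem = cohort_dir / tr["files"]["meta"].replace("_meta.json", "")
            bundle = npio.read_trial_bundle(stem)
            records.append({"participant": part["participant"],
                            "group": part["group"], "level": tr["level"],
                            "repeat": tr["repeat"], "mvc": tr["mvc"],
                            "bundle": bundle})
    log["stages"]["load"] = round(time.perf_counter() - t0, 3)

    windows: dict[int, force.SteadyWindow] = {}
    if "steadiness" in stages:
        t0 = time.perf_counter()
        rows = []
        for i, r in enumerate(records):
            tr = r["bundle"].force
            win = force.find_steadiest_window(tr)
            windows[i] = win
            rows.append({"participant": r["participant"], "group": r["group"],
                         "level": r["level"], "repeat": r["repeat"],
                         "mvc_n": r["mvc"],
                         "cov_center6s_pct": force.steadiness_cov(tr),
                         "window_start_s": win.start,
                         "window_cov_pct": win.cov})
        sdf = pd.DataFrame(rows)
        _emit(sdf, out / "steadiness.csv", seed, chash)
        # peak force vs COV regression per level (across participants)
        reg_rows = []
        per_part = sdf.groupby(["participant", "level"]).agg(
            mvc=("mvc_n", "first"), cov=("cov_center6s_pct", "mean")).reset_index()
        for level, sub in per_part.groupby("level"):
            if sub.shape[0] >= 3 and np.ptp(sub["mvc"]) > 0:
                res = force.regress_peak_vs_cov(list(zip(sub["mvc"], sub["cov"])))
                reg_rows.append({"level": level, "slope": res.slope,
                                 "slope_ci_low": res.slope_ci[0],
                                 "slope_ci_high": res.slope_ci[1],
                                 "intercept": res.intercept,
                                 "adj_r2": res.adj_r2, "n": res.n})
        if reg_rows:
            _emit(pd.DataFrame(reg_rows), out / "peak_vs_cov.csv", seed, chash)
        log["stages"]["steadiness"] = round(time.perf_counter() - t0, 3)

    def _window(i, r):
        if i in windows:
            return windows[i]
        return force.find_steadiest_window(r["bundle"].force)

    if "firing" in stages:
        t0 = time.perf_counter()
        rows = []
        for i, r in enumerate(records):
            win = _window(i, r)
            kept = firing.filter_trains(r["bundle"].spikes, win)
            for tr in kept:
                st = firing.firing_stats(tr, win, r["bundle"].force, r["mvc"])
                rows.append({"participant": r["participant"],
                             "group": r["group"], "level": r["level"],
                             "repeat": r["repeat"], "unit_id": st.unit_id,
                             "muscle": st.muscle, "rate_hz": st.mean_rate,
                             "n_ipis": st.n_ipis, "cov_ipi_pct": st.cov_ipi,
                             "threshold_pct_mvc": st.firing_threshold})
        fdf = pd.DataFrame(rows)
        _emit(fdf, out / "firing.csv", seed, chash)
        if not fdf.empty:
            mdl = fdf.rename(columns={"rate_hz": "rate",
                                      "threshold_pct_mvc": "threshold"})
            try:
                res = firing.fit_firing_lmm(mdl)
                cdf = pd.DataFrame([c.__dict__ for c in res.contrasts])
                _emit(cdf, out / "firing_contrasts.csv", seed, chash)
                (out / "firing_lmm.txt").write_text(
                    f"# seed={seed} config_hash={chash}\n"
                    f"marginal_r2={res.marginal_r2:.4f}\n"
                    f"conditional_r2={res.conditional_r2:.4f}\n"
                    f"vc_participant={res.vc_participant:.4f}\n"
                    f"vc_threshold={res.vc_threshold:.4f}\n"
                    f"resid_var={res.resid_var:.4f}\n"
                    f"singular={res.singular}\n"
                    + res.fixed_effects.to_string() + "\n")
            except ValueError as exc:
                (out / "firing_lmm.txt").write_text(
                    f"# seed={seed} config_hash={chash}\nnot fitted: {exc}\n")
        log["stages"]["firing"] = round(time.perf_counter() - t0, 3)

    if "coherence" in stages:
        t0 = time.perf_counter()
        per_trial, pooled_rows, band_rows, diff_rows, pct_rows = [], [], [], [], []
        by_group_level: dict[tuple, list] = {}
        coh_by_group_level: dict[tuple, list] = {}
        for i, r in enumerate(records):
            win = _window(i, r)
            b = r["bundle"]
            muscles = sorted(b.emg)
            envs = [coh.preprocess_envelope(b.emg[m][0], win, b.emg_fs)
                    for m in muscles[:2]]
            spec = coh.estimate_spectra(*envs)
            c = coh.coherence(spec)
            per_trial.append({"participant": r["participant"],
                              "group": r["group"], "level": r["level"],
                              "repeat": r["repeat"], "L": c.L, "cl": c.cl,
                              "crosstalk_flag": coh.crosstalk_qc(c),
                              "n_sig_bins": int(c.significant.sum())})
            key = (r["group"], r["level"])
            by_group_level.setdefault(key, []).append(spec)
            coh_by_group_level.setdefault(key, []).append(c)
        _emit(pd.DataFrame(per_trial), out / "coherence_trials.csv", seed, chash)

        pooled_by_key = {}
        for (group, level), specs in sorted(by_group_level.items()):
            pooled = coh.pool_coherence(specs)
            pooled_by_key[(group, level)] = pooled
            for f, r2, sig in zip(pooled.freqs, pooled.r2, pooled.significant):
                pooled_rows.append({"group": group, "level": level,
                                    "freq_hz": f, "pooled_r2": r2,
                                    "cl": pooled.cl, "significant": bool(sig),
                                    "reliable": f >= coh.RELIABLE_MIN_HZ})
            for b_ in coh.band_average(pooled):
                band_rows.append({"group": group, "level": level,
                                  "band": b_.band, "mean_r2": b_.mean_r2})
            pct = coh.percent_significant_trials(coh_by_group_level[(group, level)])
            for f, p in zip(pooled.freqs, pct):
                pct_rows.append({"group": group, "level": level,
                                 "freq_hz": f, "pct_significant": p})
        groups_present = sorted({g for g, _ in pooled_by_key})
        if len(groups_present) == 2:
            ga, gb = groups_present
            for level in sorted({l for _, l in pooled_by_key}):
                if (ga, level) in pooled_by_key and (gb, level) in pooled_by_key:
                    d = coh.between_group_difference(pooled_by_key[(ga, level)],
                                                    pooled_by_key[(gb, level)])
                    for f, s, up, lo in zip(d.freqs, d.statistic,
                                            d.a_greater, d.b_greater):
                        diff_rows.append({"level": level, "freq_hz": f,
                                          "statistic": s,
                                          "ci_low": d.ci_low,
                                          "ci_high": d.ci_high,
                                          f"{ga}_greater": bool(up),
                                          f"{gb}_greater": bool(lo)})
        _emit(pd.DataFrame(pooled_rows), out / "coherence_pooled.csv", seed, chash)
        _emit(pd.DataFrame(band_rows), out / "coherence_bands.csv", seed, chash)
        _emit(pd.DataFrame(pct_rows), out / "coherence_pct_significant.csv",
              seed, chash)
        if diff_rows:
            _emit(pd.DataFrame(diff_rows), out / "coherence_group_diff.csv",
                  seed, chash)
        if cfg.get("plots"):
            from .plots import plot_pooled_coherence
            plot_pooled_coherence(pooled_by_key, out / "coherence_pooled.png")
        log["stages"]["coherence"] = round(time.perf_counter() - t0, 3)

    if "cluster" in stages:
        t0 = time.perf_counter()
        dec = int(cfg["envelope_decimate"])
        rows, diag_rows = [], []
        env_by_level: dict[float, dict[str, list]] = {}
        for r in records:
            b = r["bundle"]
            if "FDS" not in b.emg:
                continue
            env = clustering.smoothed_power(b.emg["FDS"][0], b.emg_fs,
                                            participant=r["participant"],
                                            muscle="FDS", level=r["level"])
            env.samples = env.samples[::dec]
            env_by_level.setdefault(r["level"], {}).setdefault(
                r["participant"], []).append(env)
        for level, by_part in sorted(env_by_level.items()):
            avgs = [clustering.participant_average(v) for v in by_part.values()]
            if len(avgs) < 6:
                diag_rows.append({"level": level, "chosen_k": np.nan,
                                  "best_silhouette": np.nan,
                                  "supported": False,
                                  "note": "fewer than 6 participants"})
                continue
            diag = clustering.choose_k(avgs, seed=seed)
            model = clustering.kshape(avgs, diag.chosen_k, seed=seed)
            diag_rows.append({"level": level, "chosen_k": diag.chosen_k,
                              "best_silhouette": diag.silhouette[diag.chosen_k],
                              "supported": diag.supported, "note": ""})
            for env, lab in zip(avgs, model.assignments):
                rows.append({"level": level, "participant": env.participant,
                             "cluster": int(lab)})
        _emit(pd.DataFrame(diag_rows), out / "cluster_diagnostics.csv", seed, chash)
        if rows:
            _emit(pd.DataFrame(rows), out / "cluster_assignments.csv", seed, chash)
        log["stages"]["cluster"] = round(time.perf_counter() - t0, 3)

    if "stats" in stages:
        t0 = time.perf_counter()
        sdf = pd.read_csv(out / "steadiness.csv", comment="#") \
            if (out / "steadiness.csv").exists() else None
        if sdf is None:
            raise FileNotFoundError("stage 'stats': steadiness.csv missing; "
                                    "run the steadiness stage first")
        nboot = int(cfg["bootstrap_n"])
        rows = []
        groups_present = sorted(sdf["group"].unique())
        if len(groups_present) == 2:
            ga, gb = groups_present
            mvc = sdf.groupby(["participant", "group"])["mvc_n"].first().reset_index()
            a = mvc.loc[mvc.group == ga, "mvc_n"].to_numpy()
            b = mvc.loc[mvc.group == gb, "mvc_n"].to_numpy()
            comparisons = [("mvc_n", None, a, b)]
            for level, sub in sdf.groupby("level"):
                per = sub.groupby(["participant", "group"])[
                    "cov_center6s_pct"].mean().reset_index()
                comparisons.append((
                    "cov_center6s_pct", level,
                    per.loc[per.group == ga, "cov_center6s_pct"].to_numpy(),
                    per.loc[per.group == gb, "cov_center6s_pct"].to_numpy()))
            for measure, level, a_, b_ in comparisons:
                if a_.size < 2 or b_.size < 2:
                    continue
                diff = stats.boot_mean_diff(a_, b_, n=nboot, seed=seed)
                try:
                    eff = stats.boot_cohens_d(a_, b_, n=nboot, seed=seed)
                    d, lab = eff.d, eff.label
                except ValueError:
                    d, lab = np.nan, "undefined"
                rows.append({"measure": measure, "level": level,
                             "groups": f"{ga}-{gb}",
                             "estimate": diff.estimate,
                             "ci_low": diff.ci_low, "ci_high": diff.ci_high,
                             "significant": diff.significant,
                             "cohens_d": d, "label": lab})
        _emit(pd.DataFrame(rows), out / "group_comparisons.csv", seed, chash)
        log["stages"]["stats"] = round(time.perf_counter() - t0, 3)

    from . import __version__
    log["version"] = __version__
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return out
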