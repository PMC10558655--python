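"""End-to-end orchestration of the synthetic two-brain analysis.

``run_all`` executes the full stage order on generated dyads — learning
measures (SCR + value-model fits), time-frequency statistics, two-step
coupling selection with the pseudo-dyad control, NMF consensus clustering,
time-varying outcome prediction, and the ocular measures — writing each
stage's tables to a run directory with a checksummed manifest, deterministic
in the master seed (per-stage seeds are stable hashes of the stage name).

The demo dataset plants the structure the analysis is built to detect: the
low-status group's CS+ trials carry demonstrator-observer phase coupling on
"backbone" channel pairs (whole CS window) and on "pre-US" pairs (4.5-6 s
only), with a per-dyad "learning aptitude" factor driving coupling strength,
the observer's learning rate, and the conditioned pupil response; the pupil
generator additionally shares a dyadic component on CS+ trials only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import btbc, netcluster, ocular, predict, rlmodel, spectral, synth
from ._utils import as_rng, stage_seed

__all__ = ["RunConfig", "run_all", "report"]

log = logging.getLogger("dyadcoupling")

STAGES = ("synth", "learning", "tf", "btbc", "nmf", "ocular", "predict")


@dataclass
class RunConfig:
    """Declarative configuration of a full synthetic run."""
    seed: int = 1
    fs: float = 250.0
    band: str = "delta"
    n_demonstrators: int = 3
    observers_per_demonstrator: int = 10
    n_cs_plus: int = 10
    n_cs_minus: int = 10
    reinforcement_rate: float = 0.625
    schedule_start_s: float = 40.0
    n_channels: int = 6
    # backbone pairs: strong coupling over the whole CS window (CS+, LS only)
    backbone_pairs: list = field(default_factory=lambda: [
        ["D00", "O00"], ["D00", "O01"], ["D01", "O02"], ["D02", "O03"]])
    kappa_backbone: float = 0.85
    # pre-US pairs: coupling only in the late window, strength driven by the
    # per-dyad aptitude factor that also drives learning
    late_pairs: list = field(default_factory=lambda: [
        ["D01", "O04"], ["D03", "O05"]])
    late_window: list = field(default_factory=lambda: [4.5, 6.0])
    kappa_late_range: list = field(default_factory=lambda: [0.2, 0.95])
    step1_q: float = 0.05
    step2_q: float = 0.05
    nmf_ranks: list = field(default_factory=lambda: [2, 3])
    nmf_runs: int = 60
    svr: dict = field(default_factory=lambda: {"C": 1.0, "epsilon": 0.1,
                                               "gamma": "auto"})
    tf_n_perm: int = 200
    pupil_shared_gain: float = 1.0
    pupil_response_gain: float = 5.0
    hand_bias: float = 0.8
    rl_models: list = field(default_factory=lambda: ["RW-fixedV0",
                                                     "PH-fixedV0"])
    rl_n_starts: int = 8
    scr_sigma: float = 0.25

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _make_dataset(cfg: RunConfig):
    """Generate dyads, ground truth, SCR, and peripheral data."""
    rng = as_rng(stage_seed(cfg.seed, "synth"))
    band = spectral.DEFAULT_BANDS[cfg.band]
    lo, hi = cfg.kappa_late_range
    dyads = []
    dyad_id = 0
    # one schedule for all demonstrators keeps the trial clock (and recording
    # length) shared, which the pseudo-demonstrator surrogate requires
    schedule = synth.make_schedule(
        cfg.n_cs_plus, cfg.n_cs_minus, cfg.reinforcement_rate,
        seed=rng, start_s=cfg.schedule_start_s)
    for dem in range(cfg.n_demonstrators):
        for k in range(cfg.observers_per_demonstrator):
            status = "LS" if k % 2 == 0 else "HS"
            aptitude = rng.uniform(0.0, 1.0)  # drives late coupling + learning
            kappa_late = lo + (hi - lo) * aptitude
            plantings = []
            if status == "LS":
                # backbone coupling strength grows with aptitude, so NMF
                # cluster loadings track the learning outcome
                kappa_bb = cfg.kappa_backbone * (0.6 + 0.4 * aptitude)
                for d_ch, o_ch in cfg.backbone_pairs:
                    plantings.append(synth.PlantedCoupling(
                        dem_channel=d_ch, obs_channel=o_ch, band=cfg.band,
                        condition="CS+", kappa=kappa_bb))
                # pre-US coupling emerges only when the US is imminent, so
                # cumulative coupling becomes informative late in the trial
                for d_ch, o_ch in cfg.late_pairs:
                    plantings.append(synth.PlantedCoupling(
                        dem_channel=d_ch, obs_channel=o_ch, band=cfg.band,
                        condition="CS+", kappa=kappa_late,
                        window=tuple(cfg.late_window)))
            alpha = 0.1 + 0.7 * aptitude if status == "LS" else \
                rng.uniform(0.2, 0.8)
            rw = rlmodel.RWParams(V0=0.5, alpha=alpha, beta0=0.0, beta1=1.0,
                                  sigma=cfg.scr_sigma)
            gt = synth.GroundTruth(plantings=plantings,
                                   rw_params={"observer": rw},
                                   pupil_shared_gain=cfg.pupil_shared_gain,
                                   status_group=status)
            rec = synth.simulate_dyad_signals(
                schedule, plantings, band=band, fs=cfg.fs,
                n_channels=cfg.n_channels, seed=rng, ground_truth=gt)
            scr = synth.simulate_scr(schedule, rw, seed=rng)
            gain = cfg.pupil_shared_gain if status == "LS" else 0.3
            resp = cfg.pupil_response_gain * (
                aptitude if status == "LS" else rng.uniform(0.0, 1.0))
            dem_p, obs_p, fix = synth.simulate_pupil_and_fixations(
                schedule, gain, seed=rng, fs=cfg.fs,
                hand_bias=cfg.hand_bias, shared_condition="CS+",
                cs_response_gain=resp)
            dyads.append({
                "dyad_id": f"dyad{dyad_id:02d}", "demonstrator": f"dem{dem}",
                "status": status, "aptitude": aptitude,
                "kappa_late": kappa_late, "alpha_true": alpha,
                "schedule": schedule, "recording": rec, "scr": scr,
                "pupil_dem": dem_p, "pupil_obs": obs_p, "fixations": fix,
            })
            dyad_id += 1
    return dyads


def _stage_learning(cfg, dyads, out):
    rows, fit_rows, cmp_rows = [], [], []
    for d in dyads:
        sched = d["schedule"]
        scr_z = (d["scr"] - d["scr"].mean()) / d["scr"].std(ddof=1)
        for i, tr in enumerate(sched.trials):
            rows.append({"dyad_id": d["dyad_id"], "trial": i,
                         "cs_type": tr.cs_type, "us": tr.us,
                         "scr_z": scr_z[i]})
        fits = []
        for model_id in cfg.rl_models:
            fit = rlmodel.fit_rw(scr_z, sched, model_id=model_id,
                                 n_starts=cfg.rl_n_starts,
                                 seed=stage_seed(cfg.seed, f"fit:{d['dyad_id']}:{model_id}"))
            fits.append(fit)
            p = fit.params
            fit_rows.append({"dyad_id": d["dyad_id"], "model_id": model_id,
                             "V0": p.V0, "alpha": p.alpha, "beta0": p.beta0,
                             "beta1": p.beta1, "sigma": p.sigma,
                             "eta": p.eta, "loglik": fit.loglik,
                             "aic": fit.aic, "bic": fit.bic,
                             "alpha_true": d["alpha_true"]})
        ranking = rlmodel.compare_models(fits)
        ranking.insert(0, "dyad_id", d["dyad_id"])
        cmp_rows.append(ranking)
        d["alpha_fit"] = next(f for f in fits
                              if f.model_id == cfg.rl_models[0]).params.alpha
    _write(pd.DataFrame(rows), out / "learning" / "scr_trials.tsv")
    _write(pd.DataFrame(fit_rows), out / "learning" / "rw_fits.tsv")
    _write(pd.concat(cmp_rows, ignore_index=True),
           out / "learning" / "model_comparison.tsv")


def _observer_epochs(dyad, window=(-2.0, 5.5)):
    rec = dyad["recording"]
    fs = rec.fs
    n = rec.n_samples
    epochs, labels = [], []
    n_win = int(round((window[1] - window[0]) * fs))
    for tr in dyad["schedule"].trials:
        i0 = int(round((tr.onset_s + window[0]) * fs))
        if i0 < 0 or i0 + n_win > n:
            continue
        epochs.append(rec.observer_signals[:, i0:i0 + n_win])
        labels.append(tr.cs_type)
    times = np.arange(n_win) / fs + window[0]
    return np.stack(epochs), labels, times


def _stage_tf(cfg, dyads, out):
    maps_plus, maps_minus = [], []
    for d in dyads:
        epochs, labels, times = _observer_epochs(d)
        labels = np.array(labels)
        plus = epochs[labels == "CS+"]
        minus = epochs[labels == "CS-"]
        tf_p = spectral.relative_power(spectral.morlet_tf(
            plus, d["recording"].fs, times, freqs=np.arange(1.0, 9.0)))
        tf_m = spectral.relative_power(spectral.morlet_tf(
            minus, d["recording"].fs, times, freqs=np.arange(1.0, 9.0)))
        task = tf_p.times >= 0
        maps_plus.append(tf_p.power[..., task][..., ::25])
        maps_minus.append(tf_m.power[..., task][..., ::25])
    rec = dyads[0]["recording"]
    res = spectral.cluster_permutation(
        np.stack(maps_plus), np.stack(maps_minus), design="paired",
        neighbor_graph=rec.neighbor_graph,
        channel_names=rec.channel_names["observer"],
        n_perm=cfg.tf_n_perm, seed=stage_seed(cfg.seed, "tf"))
    rows = [{"cluster": i, "mass": c.mass, "p": c.p, "sign": c.sign,
             "n_voxels": len(c.voxels), "n_channels": len(c.channels)}
            for i, c in enumerate(res.clusters)]
    _write(pd.DataFrame(rows, columns=["cluster", "mass", "p", "sign",
                                       "n_voxels", "n_channels"]),
           out / "tf" / "cluster_results.tsv")


def _stage_btbc(cfg, dyads, out):
    band = spectral.DEFAULT_BANDS[cfg.band]
    genuine, pseudo = [], []
    dem_signals = {}
    for d in dyads:
        dem_signals.setdefault(d["demonstrator"],
                               d["recording"].demonstrator_signals)
    sources = list(dem_signals.values())
    for d in dyads:
        tab = btbc.epoch_coupling(d["recording"], band,
                                  dyad_id=d["dyad_id"])
        genuine.append(tab)
        surrogate = synth.make_pseudo_demonstrator(
            sources, seed=stage_seed(cfg.seed, f"pseudo:{d['dyad_id']}"))
        ptab = btbc.epoch_coupling(d["recording"], band,
                                   dyad_id=d["dyad_id"],
                                   dem_override=surrogate)
        pseudo.append(ptab)
    gtab = pd.concat(genuine, ignore_index=True)
    ptab = pd.concat(pseudo, ignore_index=True)
    _write(gtab, out / "btbc" / "coupling.tsv")

    sel = btbc.baseline_filter(gtab, q=cfg.step1_q)
    _write(sel.stats, out / "btbc" / "step1.tsv")

    status = {d["dyad_id"]: d["status"] for d in dyads}
    dem_map = {d["dyad_id"]: d["demonstrator"] for d in dyads}
    retained = sel.retained
    if retained:
        step2 = btbc.condition_contrast(
            gtab[gtab["pair"].isin(retained)], status, dem_map, q=cfg.step2_q)
    else:
        step2 = pd.DataFrame(columns=["pair", "effect", "estimate", "se",
                                      "t", "p", "q", "significant"])
    _write(step2, out / "btbc" / "step2.tsv")

    comp = btbc.pseudo_comparison(gtab, ptab)
    _write(pd.DataFrame([vars(comp)]), out / "btbc" / "pseudo.tsv")
    return gtab, sel, step2


def _stage_nmf(cfg, dyads, out, gtab, sel):
    retained = sel.retained
    if not retained:
        _write(pd.DataFrame(), out / "nmf" / "assignments.tsv")
        return None
    wide = (gtab[(gtab["epoch"] == "task") & (gtab["cs_type"] == "CS+")
                 & gtab["pair"].isin(retained)]
            .groupby(["dyad_id", "pair"], observed=True)["z_abs"].mean()
            .unstack("pair"))
    ranks = [r for r in cfg.nmf_ranks if r <= len(retained) // 2]
    if not ranks:
        ranks = [2] if len(retained) >= 4 else []
    if not ranks:
        _write(pd.DataFrame(), out / "nmf" / "assignments.tsv")
        return None
    res = netcluster.consensus_cluster(
        wide, candidate_ranks=ranks, n_runs=cfg.nmf_runs,
        seed=stage_seed(cfg.seed, "nmf"))
    _write(pd.DataFrame({"pair": res.pair_labels,
                         "cluster": res.assignments}),
           out / "nmf" / "assignments.tsv")
    _write(pd.DataFrame({"rank": list(res.cophenetic),
                         "cophenetic": list(res.cophenetic.values())}),
           out / "nmf" / "cophenetic.tsv")
    load = pd.DataFrame(res.loadings,
                        columns=[f"cluster{c}" for c in range(res.rank)])
    load.insert(0, "dyad_id", list(wide.index))
    _write(load, out / "nmf" / "loadings.tsv")

    # correlate cluster loadings with learning indices in the LS group:
    # the fitted learning rate and the differential z-scored SCR
    status = {d["dyad_id"]: d["status"] for d in dyads}
    outcomes = {"learning_rate": {d["dyad_id"]: d.get("alpha_fit", np.nan)
                                  for d in dyads},
                "differential_scr": _differential_scr(dyads)}
    ls_ids = [i for i in wide.index if status[i] == "LS"]
    rows = []
    if len(ls_ids) >= 6:
        sub = netcluster.ConsensusResult(
            rank=res.rank, consensus=res.consensus,
            assignments=res.assignments,
            loadings=load.set_index("dyad_id").loc[ls_ids].to_numpy(),
            cophenetic=res.cophenetic, pair_labels=res.pair_labels)
        for name, vals in outcomes.items():
            series = [vals[i] for i in ls_ids]
            if not np.all(np.isfinite(series)):
                continue
            corr = netcluster.loading_learning_correlation(sub, series)
            rows.append(corr.assign(group="LS", outcome=name))
    if rows:
        _write(pd.concat(rows, ignore_index=True),
               out / "nmf" / "cluster_learning.tsv")
    return res


def _differential_scr(dyads) -> dict:
    out = {}
    for d in dyads:
        scr = d["scr"]
        z = (scr - scr.mean()) / scr.std(ddof=1)
        cs = np.array(d["schedule"].cs_types)
        out[d["dyad_id"]] = float(z[cs == "CS+"].mean() - z[cs == "CS-"].mean())
    return out


def _stage_ocular(cfg, dyads, out):
    resp_rows, fix_rows, eye_rows = [], [], []
    for d in dyads:
        sched = d["schedule"]
        dem_p = ocular.preprocess_pupil(d["pupil_dem"])
        obs_p = ocular.preprocess_pupil(d["pupil_obs"])
        resp = ocular.pupil_trial_response(obs_p, sched)
        resp.insert(0, "dyad_id", d["dyad_id"])
        resp_rows.append(resp)
        prop = ocular.fixation_proportion(d["fixations"], sched)
        prop.insert(0, "dyad_id", d["dyad_id"])
        fix_rows.append(prop)
        eye = ocular.eye_coupling(dem_p, obs_p, sched)
        eye.insert(0, "dyad_id", d["dyad_id"])
        eye_rows.append(eye)
        d["pupil_diff"] = float(
            resp.loc[resp["cs_type"] == "CS+", "pupil_response"].mean()
            - resp.loc[resp["cs_type"] == "CS-", "pupil_response"].mean())
    _write(pd.concat(resp_rows, ignore_index=True),
           out / "ocular" / "pupil_responses.tsv")
    _write(pd.concat(fix_rows, ignore_index=True),
           out / "ocular" / "fixation.tsv")
    _write(pd.concat(eye_rows, ignore_index=True),
           out / "ocular" / "eye_coupling.tsv")


def _per_step_coupling(dyad, band, pairs, step_s=0.1, window=(0.0, 5.5)):
    """Mean per-0.1 s-bin z_abs over CS+ trials and the given channel pairs."""
    rec = dyad["recording"]
    fs = rec.fs
    ph_dem = spectral.band_phase(rec.demonstrator_signals, fs, band).phase
    ph_obs = spectral.band_phase(rec.observer_signals, fs, band).phase
    dem_names = rec.channel_names["demonstrator"]
    obs_names = rec.channel_names["observer"]
    d_idx = [dem_names.index(p.split("_")[0]) for p in pairs]
    o_idx = [obs_names.index(p.split("_")[1]) for p in pairs]
    n_steps = int(round((window[1] - window[0]) / step_s))
    vals = np.zeros(n_steps)
    counts = np.zeros(n_steps)
    for tr in dyad["schedule"].trials:
        if tr.cs_type != "CS+":
            continue
        for k in range(n_steps):
            t0 = tr.onset_s + window[0] + k * step_s
            i0 = int(round(t0 * fs))
            i1 = int(round((t0 + step_s) * fs))
            if i1 > ph_dem.shape[-1]:
                continue
            r = btbc.ccorr_matrix(ph_dem[d_idx, i0:i1], ph_obs[o_idx, i0:i1])
            r = r[np.arange(len(d_idx)), np.arange(len(o_idx))]
            r = r[np.isfinite(r)]
            if len(r):
                vals[k] += btbc.normalize(r).mean()
                counts[k] += 1
    counts[counts == 0] = 1
    return vals / counts


def _stage_predict(cfg, dyads, out, sel):
    band = spectral.DEFAULT_BANDS[cfg.band]
    pairs = ["_".join(p) for p in cfg.late_pairs]
    ls = [d for d in dyads if d["status"] == "LS"]
    traces = np.stack([predict.cumulative_btbc(
        _per_step_coupling(d, band, pairs)) for d in ls])
    # learning outcome: differential (CS+ - CS-) pupil response; falls back
    # to differential z-scored SCR when the ocular stage has not run
    outcomes = np.array([d.get("pupil_diff", np.nan) for d in ls])
    if np.any(~np.isfinite(outcomes)):
        diff = _differential_scr(ls)
        outcomes = np.array([diff[d["dyad_id"]] for d in ls])
    trace = predict.svr_loo_timecourse(
        traces, outcomes, kernel_params=cfg.svr,
        seed=stage_seed(cfg.seed, "predict"))
    _write(trace.table, out / "predict" / "prediction.tsv")
    onset = predict.summarize_onset(trace)
    _write(pd.DataFrame([{"onset_s": onset.onset_s,
                          "window_start_s": None if onset.window is None
                          else onset.window[0],
                          "window_end_s": None if onset.window is None
                          else onset.window[1]}]),
           out / "predict" / "onset.tsv")


def run_all(config: RunConfig, out_dir, stages=None) -> Path:
    """Run every stage on a generated dataset; returns the run directory.

    Deterministic given ``config.seed``; the manifest lists each output file
    with its SHA-256 checksum and per-stage wall time. ``stages`` restricts
    execution to a subset (the dataset itself is regenerated deterministically
    on every call); stages whose upstream results are not part of the same
    call raise an error naming the stage to rerun.
    """
    stages = set(STAGES if stages is None else stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for downstream, upstream in (("nmf", "btbc"), ("learning", "synth"),
                                 ("predict", "synth")):
        if downstream in stages and upstream not in stages:
            raise ValueError(f"stage '{downstream}' needs '{upstream}' in the "
                             f"same run; rerun with stage '{upstream}'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    timings = {}

    t0 = time.perf_counter()
    dyads = _make_dataset(config)
    if "synth" in stages:
        meta = pd.DataFrame([{k: d[k] for k in ("dyad_id", "demonstrator",
                                                "status", "aptitude",
                                                "kappa_late", "alpha_true")}
                             for d in dyads])
        _write(meta, out / "synth" / "dyads.tsv")
        dyads[0]["schedule"].to_tsv(out / "synth" / "schedule_dem0.tsv")
    timings["synth"] = time.perf_counter() - t0

    gtab = sel = None

    def stage(name, fn):
        if name not in stages:
            return
        t0 = time.perf_counter()
        log.info("stage %s (seed %d)", name, stage_seed(config.seed, name))
        fn()
        timings[name] = time.perf_counter() - t0

    stage("learning", lambda: _stage_learning(config, dyads, out))
    stage("tf", lambda: _stage_tf(config, dyads, out))

    if "btbc" in stages:
        t0 = time.perf_counter()
        gtab, sel, _ = _stage_btbc(config, dyads, out)
        timings["btbc"] = time.perf_counter() - t0

    stage("nmf", lambda: _stage_nmf(config, dyads, out, gtab, sel))
    stage("ocular", lambda: _stage_ocular(config, dyads, out))
    stage("predict", lambda: _stage_predict(config, dyads, out, sel))

    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "stages": {k: round(v, 3) for k, v in timings.items()},
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def report(run_dir, make_plots: bool = True) -> Path:
    """Summarize a completed (or partial) run into ``report.md`` (+ figures).

    Missing stages are reported as explicit gaps rather than errors.
    """
    run = Path(run_dir)
    if not (run / "manifest.json").exists():
        raise FileNotFoundError("manifest.json not found; run incomplete — "
                                "rerun run_all")
    lines = ["# dyadcoupling run report", ""]

    def section(title, path, render):
        lines.append(f"## {title}")
        f = run / path
        if not f.exists():
            lines.append("_stage output missing; section skipped_")
            lines.append("")
            return None
        df = pd.read_csv(f, sep="\t")
        render(df)
        lines.append("")
        return df

    def learning(df):
        diff = (df.pivot_table(index="dyad_id", columns="cs_type",
                               values="scr_z")
                .assign(diff=lambda t: t["CS+"] - t["CS-"]))
        lines.append(f"Mean differential SCR (CS+ - CS-): "
                     f"{diff['diff'].mean():.3f} across {len(diff)} observers")

    section("Learning (SCR + model fits)", "learning/scr_trials.tsv", learning)

    def tf(df):
        sig = df[df["p"] < 0.05] if len(df) else df
        lines.append(f"{len(df)} clusters found; {len(sig)} significant "
                     "(p < 0.05)")

    section("Time-frequency clusters", "tf/cluster_results.tsv", tf)

    def step1(df):
        n_ret = int(df["retained"].sum()) if len(df) else 0
        lines.append(f"Step 1 retained {n_ret} of {len(df)} channel pairs "
                     "(task > baseline, BH-FDR)")
        if n_ret == 0:
            lines.append("Zero retained pairs: downstream coupling sections "
                         "operate on an empty selection.")

    section("Coupling selection (step 1)", "btbc/step1.tsv", step1)

    def step2(df):
        if not len(df):
            lines.append("_no retained pairs; step 2 skipped_")
            return
        sig = df[df["significant"]]
        inter = sig[sig["effect"] == "interaction"]
        lines.append(f"Step 2: {len(sig)} significant effects across pairs; "
                     f"{len(inter)} CS-type-by-status interactions")

    section("Coupling contrasts (step 2)", "btbc/step2.tsv", step2)

    def pseudo(df):
        r = df.iloc[0]
        lines.append(
            f"Genuine vs pseudo coupling: {r['mean_genuine']:.3f} ± "
            f"{r['sd_genuine']:.3f} vs {r['mean_pseudo']:.3f} ± "
            f"{r['sd_pseudo']:.3f} (paired t = {r['t']:.2f}, p = {r['p']:.2g})")

    section("Pseudo-dyad validation", "btbc/pseudo.tsv", pseudo)

    def nmf(df):
        if not len(df):
            lines.append("_no retained pairs; clustering skipped_")
            return
        k = df["cluster"].nunique()
        lines.append(f"Consensus NMF selected {k} link communities over "
                     f"{len(df)} pairs")

    section("NMF link communities", "nmf/assignments.tsv", nmf)

    def corr(df):
        for _, r in df.iterrows():
            outcome = r.get("outcome", "learning")
            lines.append(f"- cluster {int(r['cluster'])} vs {outcome} "
                         f"({r['group']}): r = {r['r']:.2f}, "
                         f"p = {r['p']:.3g}")

    section("Cluster-learning correlations", "nmf/cluster_learning.tsv", corr)

    pred_df = None

    def pred(df):
        nonlocal pred_df
        pred_df = df
        sig = df[df["q"] < 0.05]
        best = df.loc[df["r"].idxmax()]
        lines.append(f"Peak LOO prediction r = {best['r']:.2f} at "
                     f"{best['time_s']:.1f} s; {len(sig)} of {len(df)} time "
                     "points FDR-significant")

    section("Time-varying prediction", "predict/prediction.tsv", pred)

    def fix(df):
        means = df.groupby("cs_type")[["hand", "face", "stimulus"]].mean()
        if "CS+" in means.index:
            lines.append("Mean fixation proportions (CS+): "
                         + ", ".join(f"{c} {means.loc['CS+', c]:.2f}"
                                     for c in ("hand", "face", "stimulus")))

    section("Fixations and eye coupling", "ocular/fixation.tsv", fix)

    if make_plots and pred_df is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(pred_df["time_s"], pred_df["r"], lw=1.5)
        sig = pred_df[pred_df["q"] < 0.05]
        ax.scatter(sig["time_s"], sig["r"], color="C1", s=12, zorder=3,
                   label="FDR-significant")
        ax.set_xlabel("time after CS onset (s)")
        ax.set_ylabel("LOO prediction r")
        ax.legend(loc="upper left", frameon=False)
        fig.tight_layout()
        fig.savefig(run / "prediction_r.png", dpi=120)
        plt.close(fig)
        lines.append("![prediction](prediction_r.png)")

    path = run / "report.md"
    path.write_text("\n".join(lines))
    return path
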