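"""End-to-end orchestration: data ingestion or fixture generation ->
preprocessing -> time-frequency -> burst detection -> burst statistics ->
permutation inference, with flat TSV outputs and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from burstpipe import behavior as beh
from burstpipe import bursts as bst
from burstpipe import preprocessing as prep
from burstpipe import spectral as spec
from burstpipe import stats as pstats
from burstpipe.containers import LfpRecording
from burstpipe.io import load_events_tsv, load_lfp_h5
from burstpipe.synthetic import generate_fixture

SUBCORTICAL_SITES = ("STN", "THAL_VENTRAL", "THAL_DORSAL")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either ``inputs`` (list of ``{participant, lfp, events}`` paths) or
    ``fixture`` (synthetic-session spec with ``n_participants``) must be
    given.  All windows in ms; ``n_perm`` applies to every permutation test.
    """

    inputs: list = field(default_factory=list)
    fixture: dict = field(default_factory=dict)
    line_freq: float = 60.0
    target_fs: float = 1000.0
    artifact_method: str = "zscore"  # {"manual", "zscore", "none"}
    threshold_multiplier: float = 6.0
    min_cycles: float = 2.0
    bin_width_ms: float = 100.0
    rate_window_ms: tuple = (-100.0, 900.0)
    cross_site_bin_ms: float = 50.0
    cross_site_window_ms: tuple = (-200.0, 200.0)
    n_perm: int = 10000
    seed: int = 0
    montage: str = "none"  # "bipolar" to derive adjacent-contact channels

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d


def _preprocess(rec: LfpRecording, cfg: PipelineConfig) -> LfpRecording:
    rec = prep.remove_line_noise(rec, cfg.line_freq)
    if rec.fs > cfg.target_fs:
        rec = prep.downsample_to_1khz(rec, cfg.target_fs)
    if cfg.artifact_method == "zscore":
        flags = prep.flag_artifact_segments_zscore(rec)
        if flags:
            rec = prep.reject_artifact_segments(rec, flags)
    if cfg.montage == "bipolar":
        rec = prep.make_bipolar_arrays(rec)
    return rec


def _detect_all_channels(rec: LfpRecording, cfg: PipelineConfig) -> dict[int, pd.DataFrame]:
    """Per-channel burst detection on the continuous recording."""
    params = bst.BurstDetectionParams(
        threshold_multiplier=cfg.threshold_multiplier, min_cycles=cfg.min_cycles
    )
    wspec = spec.WaveletSpec()
    out = {}
    for ci in range(rec.n_channels):
        power, valid = spec.morlet_power(rec.data[ci], rec.fs, wspec)
        med = spec.channel_median_power(power, rec.artifact_mask)
        out[ci] = bst.detect_bursts(
            power, wspec.freqs, rec.fs, med, params, valid, rec.artifact_mask
        )
    return out


def _select_channels(rec: LfpRecording, events_per_channel: dict) -> dict[str, int]:
    """One analysis channel per site: STN array with the most bursts over the
    recording (ventral-most on ties); thalamic ventral = 0-1 pair, dorsal =
    2-3 pair; SMC array as configured or localizer-selected upstream."""
    chosen: dict[str, int] = {}
    sites = rec.channels["site"]
    if (sites == "STN").any():
        counts = {i: len(ev) for i, ev in events_per_channel.items()}
        chosen["STN"] = prep.select_stn_array(rec.channels, counts)
    for site in ("THAL_VENTRAL", "THAL_DORSAL", "SMC"):
        rows = rec.channels.index[sites == site].tolist()
        if rows:
            chosen[site] = rows[0]
    return chosen


def validate_localizer(
    rec: LfpRecording,
    go_trials: pd.DataFrame,
    window_ms=(200.0, 800.0),
    suppression_db: float = -1.0,
) -> dict:
    """Score each SMC strip array for the movement-locked beta decrease.

    The score is the mean baseline-corrected beta-band (15-29 Hz) ERSP in
    200-800 ms after the go signal; the most negative (strongest
    suppression) array is selected, mirroring the intraoperative visual
    check of movement-related beta suppression.  If no array shows
    suppression, the lowest-index array is returned with a warning.
    """
    smc_rows = rec.channels.index[rec.channels["site"] == "SMC"].tolist()
    if not smc_rows:
        raise ValueError("no SMC arrays to validate")
    onset_samples = (go_trials["onset_go_ms"].to_numpy() / 1000.0 * rec.fs).astype(int)
    scores = {}
    for ci in smc_rows:
        res = spec.ersp_filter_hilbert(
            rec.data[ci],
            rec.fs,
            onset_samples,
            freqs=np.arange(15.0, 30.0),
            window_ms=(-100.0, 1500.0),
            baseline_ms=(-500.0, -200.0),
            artifact_mask=rec.artifact_mask,
        )
        sel = (res["times_ms"] >= window_ms[0]) & (res["times_ms"] < window_ms[1])
        scores[ci] = float(res["ersp"][:, sel].mean())
    best = min(scores, key=lambda c: (scores[c], c))
    if scores[best] > suppression_db:
        warnings.warn("no SMC array shows post-go beta suppression; using lowest index")
        best = smc_rows[0]
    return {"scores": scores, "selected": best}


def _analyze_participant(
    pid: str, rec: LfpRecording, trials: pd.DataFrame, cfg: PipelineConfig
) -> dict:
    """All per-participant quantities: behavior summary, per-site burst sets
    in every locking, rate matrices and derived statistics."""
    trials = beh.score_trials(trials)
    summary = beh.participant_ssrt(trials)
    ssrt = summary["ssrt"]

    matched = beh.split_matched_go(trials)
    trials = trials.merge(
        matched[["trial_index", "go_speed", "virtual_ssd_ms"]],
        on="trial_index",
        how="left",
    )

    events_per_channel = _detect_all_channels(rec, cfg)
    chosen = _select_channels(rec, events_per_channel)

    stop_trials = trials[trials["trial_kind"] == "stop"]
    matched_go = trials[trials["outcome"] == "correct-go"]
    sites = {}
    for site, ci in chosen.items():
        ev = events_per_channel[ci]
        go_locked, go_inc = bst.lock_bursts(
            ev, trials, "go", (-500.0, 1500.0), rec.artifact_mask, rec.fs
        )
        stop_locked, stop_inc = bst.lock_bursts(
            ev, stop_trials, "stop", (-500.0, 1000.0), rec.artifact_mask, rec.fs
        )
        ssd_locked, ssd_inc = bst.lock_bursts(
            ev, trials, "ssd", (-500.0, 1000.0), rec.artifact_mask, rec.fs
        )
        resp_locked, resp_inc = bst.lock_bursts(
            ev, trials, "response", (-500.0, 500.0), rec.artifact_mask, rec.fs
        )
        # SSRT-locked view: stop-locked burst times re-expressed relative to
        # the participant's SSRT (reported separately from the stop locking)
        ssrt_locked = stop_locked.copy()
        if np.isfinite(ssrt) and len(ssrt_locked):
            ssrt_locked["rel_ms"] = ssrt_locked["rel_ms"] - ssrt
        sites[site] = {
            "events": ev,
            "go_locked": (go_locked, go_inc),
            "stop_locked": (stop_locked, stop_inc),
            "ssd_locked": (ssd_locked, ssd_inc),
            "response_locked": (resp_locked, resp_inc),
            "rates_stop": bst.bin_burst_rates(
                stop_locked, stop_inc, cfg.bin_width_ms, cfg.rate_window_ms
            ),
            "rates_ssd": bst.bin_burst_rates(
                ssd_locked, ssd_inc, cfg.bin_width_ms, cfg.rate_window_ms
            ),
            "rates_go": bst.bin_burst_rates(
                go_locked, go_inc, cfg.bin_width_ms, cfg.rate_window_ms
            ),
            "rates_response": bst.bin_burst_rates(
                resp_locked, resp_inc, cfg.bin_width_ms, (-500.0, 500.0)
            ),
            "rates_ssrt": bst.bin_burst_rates(
                ssrt_locked, stop_inc, cfg.bin_width_ms, (-500.0, 500.0)
            ),
            "baselines": bst.baseline_rates(go_locked, go_inc),
            "ssd_ssrt_counts": bst.count_ssd_ssrt_bursts(go_locked, go_inc, ssrt)
            if np.isfinite(ssrt)
            else None,
            "first_bursts": bst.first_burst_latencies(stop_locked, stop_inc, ssrt),
        }

    cross = {}
    for src, tgt in (("STN", "SMC"), ("SMC", "STN")):
        if src in sites and tgt in sites:
            # seeds: stop trials use stop locking; matched go use virtual SSD
            seed_stop, inc_stop = sites[src]["stop_locked"]
            tgt_stop, _ = sites[tgt]["stop_locked"]
            cross[f"{src}->{tgt}"] = bst.cross_site_locked_rates(
                seed_stop,
                tgt_stop,
                inc_stop,
                window_ms=cfg.cross_site_window_ms,
                bin_width_ms=cfg.cross_site_bin_ms,
            )
    return {
        "pid": pid,
        "trials": trials,
        "summary": summary,
        "sites": sites,
        "cross": cross,
    }


def _group_stats(results: list[dict], cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    """Across-participant permutation ANOVAs on stop-locked burst rates and
    first-burst timing, per subcortical site."""
    out = {}
    for site in SUBCORTICAL_SITES + ("SMC",):
        mats = []
        for res in results:
            if site not in res["sites"]:
                continue
            rates = res["sites"][site]["rates_stop"]
            piv = rates.pivot(index="condition", columns="bin_start_ms", values="rate")
            piv = piv.reindex(["successful-stop", "failed-stop"])
            if piv.isna().any().any():
                continue
            mats.append(piv.to_numpy())
        if len(mats) >= 3:
            data = np.stack(mats)  # subjects x trial type x time bin
            out[f"anova_rates_{site}"] = pstats.perm_rm_anova(
                data,
                n_perm=cfg.n_perm,
                seed=int(rng.integers(2**31 - 1)),
                factor_names=("trial type", "timepoint"),
            )
            # pairwise trial-type contrasts per time bin, Holm-corrected
            edges = np.arange(
                cfg.rate_window_ms[0], cfg.rate_window_ms[1], cfg.bin_width_ms
            )
            contrasts = [
                (
                    f"successful-vs-failed@{int(edges[b])}ms",
                    data[:, 0, b],
                    data[:, 1, b],
                )
                for b in range(data.shape[2])
            ]
            out[f"pairwise_rates_{site}"] = pstats.holm_pairwise(contrasts)
    # first-burst timing: mixed ANOVA with between factor = subcortical location
    lat_rows = []
    for res in results:
        for site in ("STN", "THAL_DORSAL"):
            if site not in res["sites"]:
                continue
            fb = res["sites"][site]["first_bursts"]
            means = fb.groupby("outcome")["latency_stop_ms"].mean()
            if {"successful-stop", "failed-stop"} <= set(means.index):
                lat_rows.append(
                    {
                        "pid": res["pid"],
                        "site": site,
                        "succ": means["successful-stop"],
                        "fail": means["failed-stop"],
                    }
                )
    lat = pd.DataFrame(lat_rows)
    if len(lat) >= 4 and lat["site"].nunique() == 2:
        groups = (lat["site"] == "STN").astype(int).to_numpy()
        if min((groups == 0).sum(), (groups == 1).sum()) >= 2:
            out["anova_burst_timing"] = pstats.mixed_anova_burst_timing(
                lat[["succ", "fail"]].to_numpy(),
                groups,
                n_perm=min(cfg.n_perm, 2000),
                seed=int(rng.integers(2**31 - 1)),
            )
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full analysis and write TSV tables, logs and a manifest.

    Returns the output directory.  Every run is deterministic for a fixed
    (config, seed); the manifest stores the resolved config and its hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- load or simulate participants -------------------------------
    sessions: list[tuple[str, LfpRecording, pd.DataFrame]] = []
    if config.fixture:
        fx = dict(config.fixture)
        n_participants = int(fx.pop("n_participants", 1))
        for p in range(n_participants):
            sim = generate_fixture(fx, seed=config.seed * 1000 + p)
            sessions.append((f"sim{p:02d}", sim["recording"], sim["trials"]))
    elif config.inputs:
        for item in config.inputs:
            rec = load_lfp_h5(item["lfp"])
            trials = load_events_tsv(item["events"])
            sessions.append((str(item.get("participant", item["lfp"])), rec, trials))
    else:
        raise ValueError("config must provide either inputs or fixture")

    # ---- behavior scoring + exclusions -------------------------------
    scored = {pid: beh.score_trials(tr) for pid, _, tr in sessions}
    kept, excl_report = beh.apply_exclusions(scored)
    excl_report.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)

    results = []
    for pid, rec, _ in sessions:
        if pid not in kept:
            continue
        rec = _preprocess(rec, config)
        results.append(_analyze_participant(pid, rec, kept[pid], config))
    if not results:
        raise ValueError("no participants survive exclusions")

    # ---- write per-participant tables --------------------------------
    beh_rows = [{"participant": r["pid"], **r["summary"]} for r in results]
    pd.DataFrame(beh_rows).to_csv(out_dir / "behavior_summary.tsv", sep="\t", index=False)

    summ_rows, rate_frames, base_frames, count_frames, fb_frames, cross_frames = (
        [], [], [], [], [], []
    )
    for r in results:
        for site, s in r["sites"].items():
            if len(s["events"]):
                summ = bst.summarize_bursts(s["events"])
                summ_rows.append(
                    {
                        "participant": r["pid"],
                        "site": site,
                        "n_bursts": int(summ["n_bursts"][0]),
                        "mean_freq_hz": summ["mean_freq_hz"][0],
                        "mean_duration_ms": summ["mean_duration_ms"][0],
                    }
                )
            for key, name in (
                ("rates_stop", "stop"),
                ("rates_ssd", "ssd"),
                ("rates_go", "go"),
                ("rates_response", "response"),
                ("rates_ssrt", "ssrt"),
            ):
                df = s[key].copy()
                df.insert(0, "participant", r["pid"])
                df.insert(1, "site", site)
                df.insert(2, "lock", name)
                rate_frames.append(df)
            df = s["baselines"].copy()
            df.insert(0, "participant", r["pid"])
            df.insert(1, "site", site)
            base_frames.append(df)
            if s["ssd_ssrt_counts"] is not None:
                df = s["ssd_ssrt_counts"].copy()
                df.insert(0, "participant", r["pid"])
                df.insert(1, "site", site)
                count_frames.append(df)
            df = s["first_bursts"].copy()
            df.insert(0, "participant", r["pid"])
            df.insert(1, "site", site)
            fb_frames.append(df)
        for pair, df in r["cross"].items():
            df = df.copy()
            df.insert(0, "participant", r["pid"])
            df.insert(1, "pair", pair)
            cross_frames.append(df)

    pd.DataFrame(summ_rows).to_csv(out_dir / "burst_summary.tsv", sep="\t", index=False)
    pd.concat(rate_frames).to_csv(out_dir / "burst_rates.tsv", sep="\t", index=False)
    pd.concat(base_frames).to_csv(out_dir / "baseline_rates.tsv", sep="\t", index=False)
    if count_frames:
        pd.concat(count_frames).to_csv(
            out_dir / "ssd_ssrt_counts.tsv", sep="\t", index=False
        )
    pd.concat(fb_frames).to_csv(
        out_dir / "first_burst_latencies.tsv", sep="\t", index=False
    )
    if cross_frames:
        pd.concat(cross_frames).to_csv(
            out_dir / "cross_site_rates.tsv", sep="\t", index=False
        )

    # ---- group inference ---------------------------------------------
    stats_tables = _group_stats(results, config, rng)
    for name, df in stats_tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)

    resolved = config.to_dict()
    cfg_json = json.dumps(resolved, sort_keys=True, default=str)
    from burstpipe import __version__ as _version  # deferred: avoids import cycle

    manifest = {
        "burstpipe_version": _version,
        "seed": config.seed,
        "config": resolved,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_participants_input": len(sessions),
        "n_participants_analyzed": len(results),
        "n_exclusions": int(len(excl_report)),
        "outputs": sorted(p.name for p in out_dir.glob("*.tsv")),
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return out_dir
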