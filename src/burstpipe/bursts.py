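"""Beta-burst detection and burst-derived statistics.

A burst is a local maximum of trial-by-trial Morlet time-frequency power in
the 15-29 Hz band that exceeds six times the channel's median power (median
taken per frequency across the whole artifact-free recording) and stays
above that threshold for at least two cycles at its peak frequency.  Each
burst is quantified once, at its center (time of maximal power), with its
peak frequency, power relative to the median, and supra-threshold duration.

All window conventions are half-open [a, b) in ms relative to the locking
event (0 = event onset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from burstpipe.spectral import BETA_BAND


@dataclass
class BurstDetectionParams:
    band: tuple = BETA_BAND
    threshold_multiplier: float = 6.0
    min_cycles: float = 2.0
    epoch_window_ms: tuple = (-500.0, 1000.0)
    merge_freq_hz: float = 3.0

    def __post_init__(self):
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")


def _local_maxima(rel: np.ndarray) -> np.ndarray:
    """Boolean mask of samples strictly greater than their 8 neighbors in
    the (frequency x time) grid; grid-boundary cells use existing
    neighbors only."""
    F, T = rel.shape
    pad = np.full((F + 2, T + 2), -np.inf)
    pad[1:-1, 1:-1] = rel
    center = pad[1:-1, 1:-1]
    mask = np.ones((F, T), dtype=bool)
    for df in (-1, 0, 1):
        for dt in (-1, 0, 1):
            if df == 0 and dt == 0:
                continue
            mask &= center > pad[1 + df : 1 + df + F, 1 + dt : 1 + dt + T]
    return mask


def detect_bursts(
    power: np.ndarray,
    freqs: np.ndarray,
    fs: float,
    median_per_freq: np.ndarray,
    params: BurstDetectionParams | None = None,
    valid: np.ndarray | None = None,
    artifact_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Detect beta bursts in continuous time-frequency power.

    Parameters
    ----------
    power : (n_freqs, n_samples) Morlet power of one channel.
    freqs : frequency axis in Hz.
    median_per_freq : per-frequency median power of the same channel across
        the artifact-free recording (the threshold anchor).
    valid : optional boolean array matching ``power``; False marks
        edge-affected samples whose maxima are discarded.
    artifact_mask : optional per-sample boolean; bursts centered on masked
        samples are discarded.

    Returns a DataFrame with columns ``t_ms`` (absolute center time),
    ``freq_hz``, ``power_x_median`` and ``duration_ms``, sorted by time.
    Overlapping maxima (within 3 Hz and one burst-duration of a larger
    maximum) are merged into the larger one so a single physiological event
    is counted once.
    """
    params = params or BurstDetectionParams()
    median_per_freq = np.asarray(median_per_freq, dtype=float)
    if np.any(median_per_freq <= 0):
        raise ValueError("degenerate channel: median power is zero")
    rel = power / median_per_freq[:, None]
    thr = params.threshold_multiplier

    cand = _local_maxima(rel) & (rel > thr)
    if valid is not None:
        cand &= valid
    if artifact_mask is not None:
        cand &= ~np.asarray(artifact_mask, dtype=bool)[None, :]

    fi, ti = np.nonzero(cand)
    order = np.argsort(rel[fi, ti])[::-1]  # descending power
    fi, ti = fi[order], ti[order]

    accepted: list[dict] = []
    for f_idx, t_idx in zip(fi, ti):
        f = freqs[f_idx]
        row_above = rel[f_idx] > thr
        # contiguous supra-threshold run at the peak frequency containing the peak
        left = t_idx
        while left > 0 and row_above[left - 1]:
            left -= 1
        right = t_idx
        n = row_above.size
        while right < n - 1 and row_above[right + 1]:
            right += 1
        duration_ms = (right - left + 1) / fs * 1000.0
        if duration_ms < params.min_cycles * 1000.0 / f:
            continue
        t_ms = t_idx / fs * 1000.0
        merged = False
        for acc in accepted:
            if (
                abs(acc["freq_hz"] - f) <= params.merge_freq_hz
                and abs(acc["t_ms"] - t_ms) <= acc["duration_ms"]
            ):
                merged = True
                break
        if merged:
            continue
        accepted.append(
            {
                "t_ms": t_ms,
                "freq_hz": float(f),
                "power_x_median": float(rel[f_idx, t_idx]),
                "duration_ms": duration_ms,
            }
        )
    cols = ["t_ms", "freq_hz", "power_x_median", "duration_ms"]
    out = pd.DataFrame(accepted, columns=cols)
    return out.sort_values("t_ms").reset_index(drop=True)


def _lock_times(trials: pd.DataFrame, lock: str) -> pd.Series:
    """Absolute locking time (ms) per trial; NaN where the lock is undefined."""
    onset = trials["onset_go_ms"]
    if lock == "go":
        return onset.astype(float)
    if lock == "stop":
        return onset + trials["ssd_ms"]
    if lock == "response":
        return onset + trials["rt_ms"]
    if lock == "ssd":
        # actual SSD on stop trials, staircase (virtual) SSD on go trials
        ssd = trials["ssd_ms"].where(
            np.isfinite(trials["ssd_ms"]), trials["staircase_ssd_ms"]
        )
        return onset + ssd
    raise ValueError(f"unknown lock {lock!r}")


def lock_bursts(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    lock: str,
    window_ms: tuple = (-500.0, 1000.0),
    artifact_mask: np.ndarray | None = None,
    fs: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map absolute burst times into lock-relative epochs.

    Returns ``(locked_events, included_trials)``: events get ``trial_index``
    and ``rel_ms`` (center time minus lock time, kept when in
    [window_ms[0], window_ms[1]) ); trials whose epoch overlaps an artifact-
    masked sample, or whose lock is undefined, are dropped from
    ``included_trials`` (the rate denominators).
    """
    lock_t = _lock_times(trials, lock)
    t_abs = events["t_ms"].to_numpy(dtype=float) if len(events) else np.empty(0)
    rows = []
    keep_trials = []
    for pos, (idx, tr) in enumerate(trials.iterrows()):
        t0 = lock_t.iloc[pos]
        if not np.isfinite(t0):
            continue
        if artifact_mask is not None:
            a = int(round((t0 + window_ms[0]) / 1000.0 * fs))
            b = int(round((t0 + window_ms[1]) / 1000.0 * fs))
            a, b = max(a, 0), min(b, artifact_mask.size)
            if a >= b or artifact_mask[a:b].any():
                continue
        keep_trials.append(idx)
        sel = (t_abs - t0 >= window_ms[0]) & (t_abs - t0 < window_ms[1])
        for ei in np.flatnonzero(sel):
            row = events.iloc[ei].to_dict()
            row["trial_index"] = tr["trial_index"]
            row["rel_ms"] = t_abs[ei] - t0
            rows.append(row)
    locked = pd.DataFrame(
        rows, columns=list(events.columns) + ["trial_index", "rel_ms"]
    )
    return locked, trials.loc[keep_trials]


def summarize_bursts(events: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Mean peak frequency (Hz), duration (ms) and count, optionally grouped."""
    if len(events) == 0:
        raise ValueError("no bursts to summarize")
    if by is None:
        grp = [("all", events)]
    else:
        grp = events.groupby(by)
    rows = []
    for key, ev in grp:
        rows.append(
            {
                "group": key,
                "n_bursts": len(ev),
                "mean_freq_hz": float(ev["freq_hz"].mean()),
                "mean_duration_ms": float(ev["duration_ms"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _condition_of(trials: pd.DataFrame) -> pd.Series:
    """Per-trial condition: stop outcomes as-is, correct go split fast/slow
    when a ``go_speed`` column is present."""
    cond = trials["outcome"].copy()
    if "go_speed" in trials.columns:
        is_go = trials["outcome"] == "correct-go"
        cond[is_go] = trials.loc[is_go, "go_speed"].astype(str) + "-go"
    return cond


def bin_burst_rates(
    locked: pd.DataFrame,
    trials: pd.DataFrame,
    bin_width_ms: float = 100.0,
    window_ms: tuple = (-100.0, 900.0),
) -> pd.DataFrame:
    """Mean bursts per trial per time bin and condition.

    rate(condition, bin) = (number of bursts with center in [a, b)) /
    (number of trials of that condition).  Bookkeeping identity: sum over
    bins of rate * n_trials = number of in-window bursts.
    """
    edges = np.arange(window_ms[0], window_ms[1] + bin_width_ms, bin_width_ms)
    cond = _condition_of(trials)
    rows = []
    for c in cond.unique():
        tr_idx = trials.loc[cond == c, "trial_index"]
        n_tr = len(tr_idx)
        ev = locked[locked["trial_index"].isin(tr_idx)] if len(locked) else locked
        for a, b in zip(edges[:-1], edges[1:]):
            cnt = (
                int(((ev["rel_ms"] >= a) & (ev["rel_ms"] < b)).sum())
                if len(ev)
                else 0
            )
            rows.append(
                {
                    "condition": c,
                    "bin_start_ms": a,
                    "bin_stop_ms": b,
                    "rate": cnt / n_tr if n_tr else np.nan,
                    "n_trials": n_tr,
                }
            )
    return pd.DataFrame(rows)


def count_ssd_ssrt_bursts(
    go_locked: pd.DataFrame, trials: pd.DataFrame, ssrt: float
) -> pd.DataFrame:
    """Mean burst count in the trial-specific [SSD, SSD + SSRT) window.

    Go-locked burst centers are counted between each trial's SSD (actual on
    stop trials, staircase-virtual on matched go trials) and SSD + the
    participant's SSRT, then averaged per condition {successful-stop,
    failed-stop, fast-go, slow-go}.
    """
    if not np.isfinite(ssrt) or ssrt < 0:
        raise ValueError("ssrt must be finite and >= 0")
    cond = _condition_of(trials)
    counts = []
    for pos, (_, tr) in enumerate(trials.iterrows()):
        ssd = tr["ssd_ms"] if np.isfinite(tr["ssd_ms"]) else tr.get("virtual_ssd_ms", tr["staircase_ssd_ms"])
        if not np.isfinite(ssd):
            counts.append(np.nan)
            continue
        ev = go_locked[go_locked["trial_index"] == tr["trial_index"]]
        counts.append(
            int(((ev["rel_ms"] >= ssd) & (ev["rel_ms"] < ssd + ssrt)).sum())
            if len(ev)
            else 0
        )
    df = pd.DataFrame({"condition": cond.to_numpy(), "count": counts})
    out = (
        df.dropna()
        .groupby("condition")["count"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_count", "size": "n_trials"})
    )
    return out


def baseline_rates(
    go_locked: pd.DataFrame, trials: pd.DataFrame, window_ms: float = 100.0
) -> pd.DataFrame:
    """Burst rates in the 100 ms before the go signal and before SSD.

    Both windows are half-open: [-100, 0) before go, [SSD-100, SSD) before
    the (actual or virtual) stop signal; counts are averaged over trials per
    condition to confirm conditions do not differ before the stop signal.
    """
    cond = _condition_of(trials)
    rows = []
    for c in cond.unique():
        sub = trials[cond == c]
        n = len(sub)
        pre_go = 0
        pre_stop = 0
        for _, tr in sub.iterrows():
            ev = go_locked[go_locked["trial_index"] == tr["trial_index"]]
            if len(ev):
                pre_go += int(((ev["rel_ms"] >= -window_ms) & (ev["rel_ms"] < 0)).sum())
                ssd = (
                    tr["ssd_ms"]
                    if np.isfinite(tr["ssd_ms"])
                    else tr["staircase_ssd_ms"]
                )
                if np.isfinite(ssd):
                    pre_stop += int(
                        ((ev["rel_ms"] >= ssd - window_ms) & (ev["rel_ms"] < ssd)).sum()
                    )
        rows.append(
            {
                "condition": c,
                "pre_go_rate": pre_go / n if n else np.nan,
                "pre_stop_rate": pre_stop / n if n else np.nan,
                "n_trials": n,
            }
        )
    return pd.DataFrame(rows)


def first_burst_latencies(
    stop_locked: pd.DataFrame,
    trials: pd.DataFrame,
    ssrt: float,
    window_ms: tuple = (0.0, 1000.0),
) -> pd.DataFrame:
    """Latency of the first burst after the stop signal, per trial.

    The first burst center in (0, 1000] ms after the stop signal; the
    SSRT-relative latency is the stop-locked latency minus the participant's
    SSRT.  Trials without a burst in the window yield NaN (excluded from
    means).
    """
    rows = []
    for _, tr in trials.iterrows():
        ev = stop_locked[stop_locked["trial_index"] == tr["trial_index"]]
        ev = ev[(ev["rel_ms"] > window_ms[0]) & (ev["rel_ms"] <= window_ms[1])]
        lat = float(ev["rel_ms"].min()) if len(ev) else np.nan
        rows.append(
            {
                "trial_index": tr["trial_index"],
                "outcome": tr["outcome"],
                "latency_stop_ms": lat,
                "latency_ssrt_ms": lat - ssrt if np.isfinite(lat) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cross_site_locked_rates(
    seed_locked: pd.DataFrame,
    target_locked: pd.DataFrame,
    trials: pd.DataFrame,
    seed_window_ms: tuple = (0.0, 500.0),
    window_ms: tuple = (-200.0, 200.0),
    bin_width_ms: float = 50.0,
) -> pd.DataFrame:
    """Target-site burst rate time-locked to the first seed-site burst.

    The seed is the first site-A burst in (0, 500] ms after the stop signal
    (or after the virtual SSD on matched go trials); for every site-B burst
    in the same trial the latency difference (target - seed) is histogrammed
    in 50-ms bins over [-200, 200) ms and divided by the number of seed
    trials per condition.  Trials without a seed burst are excluded.
    """
    edges = np.arange(window_ms[0], window_ms[1] + bin_width_ms, bin_width_ms)
    cond = _condition_of(trials)
    rows = []
    for c in cond.unique():
        sub = trials[cond == c]
        counts = np.zeros(len(edges) - 1)
        n_seed_trials = 0
        for _, tr in sub.iterrows():
            sd = seed_locked[seed_locked["trial_index"] == tr["trial_index"]]
            sd = sd[(sd["rel_ms"] > seed_window_ms[0]) & (sd["rel_ms"] <= seed_window_ms[1])]
            if not len(sd):
                continue
            n_seed_trials += 1
            t_seed = float(sd["rel_ms"].min())
            tg = target_locked[target_locked["trial_index"] == tr["trial_index"]]
            if not len(tg):
                continue
            delta = tg["rel_ms"].to_numpy(dtype=float) - t_seed
            hist, _ = np.histogram(delta, bins=edges)
            counts += hist
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            rows.append(
                {
                    "condition": c,
                    "bin_start_ms": a,
                    "bin_stop_ms": b,
                    "rate": counts[k] / n_seed_trials if n_seed_trials else np.nan,
                    "n_seed_trials": n_seed_trials,
                }
            )
    return pd.DataFrame(rows)
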