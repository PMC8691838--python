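"""Synthetic stop-signal-task behavior and multi-site LFP with known burst timing.

The behavioral generator implements the independent horse-race model: on each
trial an exGaussian go process races a stop process of fixed latency
(``ssrt_true``) started at the current stop-signal delay (SSD).  The SSD is
staircased per responding hand in 50-ms steps (1-up/1-down, floor 0 ms,
initial 250 ms) so that stopping accuracy converges on 50%.

The LFP generator produces 1/f background noise per recording site and
injects Gaussian-windowed beta-band (15-29 Hz) sinusoids ("bursts") whose
times follow inhomogeneous Poisson rate profiles tied to each trial's go /
stop / response events.  Directed coupling rules add a burst at a target site
a fixed lag after a source-site burst with a stated probability, emulating
the cross-regional burst sequences the pipeline is designed to measure.
Every injected event is recorded in a ground-truth log so downstream
detection and timing statistics can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from burstpipe.containers import LfpRecording
from burstpipe.io import save_events_tsv, save_lfp_h5

SITES = ("STN", "THAL_VENTRAL", "THAL_DORSAL", "SMC")

TRIAL_LENGTH_MS = 4000  # go signal every 4 s: 2 s response window + 2 s ITI
SESSION_PAD_MS = 1000  # silence before the first go and after the last trial


@dataclass
class BehaviorGenParams:
    """Parameters of the race-model behavior generator (durations in ms)."""

    go_rt_mu: float = 500.0
    go_rt_sigma: float = 50.0
    go_rt_tau: float = 100.0
    ssrt_true: float = 250.0
    p_trigger_failure: float = 0.0
    n_trials: int = 192
    p_stop: float = 1.0 / 3.0
    ssd_init: float = 250.0
    ssd_step: float = 50.0
    response_deadline: float = 2000.0
    iti: float = 2000.0
    p_wrong_press: float = 0.0
    trials_per_block: int = 48
    seed: int = 0

    def validate(self) -> None:
        durations = (
            self.go_rt_mu,
            self.go_rt_sigma,
            self.go_rt_tau,
            self.response_deadline,
            self.iti,
            self.ssd_step,
        )
        if not all(np.isfinite(d) and d > 0 for d in durations):
            raise ValueError("all durations must be finite and > 0")
        if not (np.isfinite(self.ssrt_true) and self.ssrt_true >= 0):
            raise ValueError("ssrt_true must be finite and >= 0")
        if not (np.isfinite(self.ssd_init) and self.ssd_init >= 0):
            raise ValueError("ssd_init must be finite and >= 0")
        for p in (self.p_trigger_failure, self.p_stop, self.p_wrong_press):
            if not (np.isfinite(p) and 0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class RateWindow:
    """Additive burst-rate modulation in a window around a trial event.

    ``lock`` is one of ``go``, ``stop``, ``response``; the window
    [start_ms, end_ms) is relative to that event and ``delta`` (bursts/s) is
    added to the baseline rate for trials whose kind or outcome is in
    ``conditions`` (empty tuple = all trials).
    """

    lock: str
    start_ms: float
    end_ms: float
    delta: float
    conditions: tuple = ()


@dataclass
class SiteRateProfile:
    baseline: float = 0.3  # bursts/s
    windows: list = field(default_factory=list)


@dataclass
class CouplingRule:
    """Directed burst coupling: each source-site burst spawns a target-site
    burst at +lag_ms with the given probability."""

    source: str
    target: str
    lag_ms: float
    probability: float


def default_rate_profiles() -> dict:
    """Rate profiles emulating the reported burst dynamics: subcortical burst
    rates rise in the 500 ms after the stop signal (more on successful than
    failed stops) and fall around the response; SMC bursting is driven by
    STN coupling plus its own baseline.  Absolute rates in bursts/s are free
    parameters of the generator."""
    post_stop = [
        RateWindow("stop", 0, 500, 1.6, ("successful-stop",)),
        RateWindow("stop", 0, 500, 0.8, ("failed-stop",)),
    ]
    peri_resp = [RateWindow("response", -200, 200, -0.25)]
    return {
        "STN": SiteRateProfile(0.3, post_stop + peri_resp),
        "THAL_VENTRAL": SiteRateProfile(0.3, post_stop + peri_resp),
        "THAL_DORSAL": SiteRateProfile(0.3, post_stop + peri_resp),
        "SMC": SiteRateProfile(0.3, peri_resp),
    }


@dataclass
class LfpGenParams:
    """Parameters of the synthetic LFP generator."""

    sites: tuple = SITES
    fs: float = 1000.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    burst_freq_range: tuple = (15.0, 29.0)
    burst_duration_mean_ms: float = 130.0
    burst_duration_sd_ms: float = 20.0
    burst_amp_snr: float = 10.0
    rate_profiles: dict = field(default_factory=default_rate_profiles)
    coupling: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 500:
            raise ValueError("fs must be >= 500 Hz")
        lo, hi = self.burst_freq_range
        if not (15.0 <= lo <= hi <= 29.0):
            raise ValueError("burst_freq_range must lie within [15, 29] Hz")
        if self.burst_amp_snr <= 0 or self.noise_scale <= 0:
            raise ValueError("amplitudes must be positive")
        for rule in self.coupling:
            if rule.lag_ms < 0:
                raise ValueError("coupling lag must be >= 0")
            if not 0 <= rule.probability <= 1:
                raise ValueError("coupling probability must lie in [0, 1]")
        for prof in self.rate_profiles.values():
            if prof.baseline < 0:
                raise ValueError("baseline rates must be >= 0")


def _exgauss(rng: np.random.Generator, mu, sigma, tau, size) -> np.ndarray:
    return rng.normal(mu, sigma, size) + rng.exponential(tau, size)


def simulate_behavior(params: BehaviorGenParams) -> pd.DataFrame:
    """Simulate one session of the stop-signal task.

    Returns a trial table with the events-TSV schema.  Stop trials carry the
    SSD used; every trial stores the current staircase value for its hand
    (``staircase_ssd_ms``), which serves as the matched-go virtual SSD.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_trials

    hands = rng.choice(["left", "right"], size=n)
    is_stop = rng.random(n) < params.p_stop
    go_rts = _exgauss(rng, params.go_rt_mu, params.go_rt_sigma, params.go_rt_tau, n)
    go_rts = np.maximum(go_rts, 1.0)
    wrong = rng.random(n) < params.p_wrong_press
    trig_fail = rng.random(n) < params.p_trigger_failure

    staircase = {"left": params.ssd_init, "right": params.ssd_init}
    rows = []
    for i in range(n):
        hand = hands[i]
        onset = SESSION_PAD_MS + i * TRIAL_LENGTH_MS
        ssd = staircase[hand]
        rt = go_rts[i]
        rec = {
            "trial_index": i,
            "block": i // params.trials_per_block,
            "onset_go_ms": float(onset),
            "trial_kind": "stop" if is_stop[i] else "go",
            "ssd_ms": np.nan,
            "staircase_ssd_ms": float(ssd),
            "rt_ms": np.nan,
            "hand": hand,
            "pressed": "",
            "outcome": "",
        }
        if is_stop[i]:
            rec["ssd_ms"] = float(ssd)
            # stop wins unless the go finishes first or the stop never triggers
            responded = trig_fail[i] or (rt < ssd + params.ssrt_true)
            if responded and rt <= params.response_deadline:
                rec["rt_ms"] = float(rt)
                rec["pressed"] = (
                    ("right" if hand == "left" else "left") if wrong[i] else hand
                )
                rec["outcome"] = "failed-stop"
                staircase[hand] = max(0.0, ssd - params.ssd_step)
            else:
                rec["outcome"] = "successful-stop"
                staircase[hand] = ssd + params.ssd_step
        else:
            if rt > params.response_deadline:
                rec["outcome"] = "go-omission"
            elif wrong[i]:
                rec["rt_ms"] = float(rt)
                rec["pressed"] = "right" if hand == "left" else "left"
                rec["outcome"] = "wrong-go"
            else:
                rec["rt_ms"] = float(rt)
                rec["pressed"] = hand
                rec["outcome"] = "correct-go"
        rows.append(rec)
    return pd.DataFrame(rows)


def one_over_f_noise(
    rng: np.random.Generator, n_samples: int, fs: float, exponent: float, scale: float
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, unit-free std = scale."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n=n_samples)
    return shaped / shaped.std() * scale


def _band_rms(x: np.ndarray, fs: float, band=(15.0, 29.0)) -> float:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return float(sps.sosfiltfilt(sos, x).std())


def burst_waveform(
    fs: float, freq: float, duration_ms: float, amp: float, snr_for_width: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid.

    The envelope SD is set so that the full width at the level where the
    envelope crosses the sqrt(6)-times-median amplitude (i.e. the 6x-median
    power threshold of the detector, assuming peak amplitude = snr_for_width
    times the background RMS) approximately equals ``duration_ms``.
    """
    ratio = snr_for_width / np.sqrt(6.0)
    if ratio <= 1.2:
        sigma_s = duration_ms / 1000.0 / 4.0
    else:
        sigma_s = duration_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(ratio)))
    half = int(round(4 * sigma_s * fs))
    t = np.arange(-half, half + 1) / fs
    return amp * np.exp(-(t**2) / (2 * sigma_s**2)) * np.sin(2 * np.pi * freq * t)


def _event_rate_grid(
    trials: pd.DataFrame, profile: SiteRateProfile, n_ms: int, grid_ms: int
) -> np.ndarray:
    """Piecewise-constant burst rate (bursts/s) over the session on a grid."""
    n_bins = n_ms // grid_ms
    rate = np.full(n_bins, profile.baseline)
    for w in profile.windows:
        for _, tr in trials.iterrows():
            if w.conditions and tr["outcome"] not in w.conditions and tr[
                "trial_kind"
            ] not in w.conditions:
                continue
            if w.lock == "go":
                t0 = tr["onset_go_ms"]
            elif w.lock == "stop":
                if not np.isfinite(tr["ssd_ms"]):
                    continue
                t0 = tr["onset_go_ms"] + tr["ssd_ms"]
            elif w.lock == "response":
                if not np.isfinite(tr["rt_ms"]):
                    continue
                t0 = tr["onset_go_ms"] + tr["rt_ms"]
            else:
                raise ValueError(f"unknown lock {w.lock!r}")
            a = int(np.floor((t0 + w.start_ms) / grid_ms))
            b = int(np.ceil((t0 + w.end_ms) / grid_ms))
            rate[max(a, 0) : max(min(b, n_bins), 0)] += w.delta
    return np.maximum(rate, 0.0)


def simulate_lfp(
    trials: pd.DataFrame, params: LfpGenParams
) -> tuple[LfpRecording, pd.DataFrame]:
    """Generate per-site LFP and the ground-truth log of injected bursts.

    Returns ``(recording, truth_log)``.  The truth log has one row per
    injected waveform: site, trial_index (trial whose 4-s window contains the
    burst center, -1 otherwise), t_center_ms (absolute), freq_hz, amp,
    duration_ms, coupled (bool: spawned by a coupling rule).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    grid_ms = 10

    session_ms = int(trials["onset_go_ms"].max() + TRIAL_LENGTH_MS + SESSION_PAD_MS)
    n_samples = int(round(session_ms / 1000.0 * params.fs))
    if trials["onset_go_ms"].min() < 0:
        raise ValueError("trial onsets must be non-negative")

    lo, hi = params.burst_freq_range
    min_cycles = 2.0

    def draw_event(t_ms: float, site: str, coupled: bool) -> dict:
        f = rng.uniform(lo, hi)
        dur = rng.normal(params.burst_duration_mean_ms, params.burst_duration_sd_ms)
        dur = max(dur, min_cycles * 1000.0 / f)
        return {
            "site": site,
            "t_center_ms": float(t_ms),
            "freq_hz": float(f),
            "duration_ms": float(dur),
            "coupled": coupled,
        }

    # 1) draw primary events per site from the inhomogeneous Poisson profiles
    events: list[dict] = []
    for site in params.sites:
        profile = params.rate_profiles.get(site, SiteRateProfile())
        rate = _event_rate_grid(trials, profile, session_ms, grid_ms)
        counts = rng.poisson(rate * grid_ms / 1000.0)
        for b in np.flatnonzero(counts):
            for _ in range(counts[b]):
                t = (b + rng.random()) * grid_ms
                events.append(draw_event(t, site, coupled=False))

    # 2) coupling rules spawn target events off the primary events
    for rule in params.coupling:
        for ev in [e for e in events if e["site"] == rule.source and not e["coupled"]]:
            if rng.random() < rule.probability:
                t = ev["t_center_ms"] + rule.lag_ms
                if 0 < t < session_ms:
                    events.append(draw_event(t, rule.target, coupled=True))

    # 3) synthesize signals: 1/f noise + injected waveforms
    data = np.zeros((len(params.sites), n_samples))
    amps = []
    for si, site in enumerate(params.sites):
        noise = one_over_f_noise(
            rng, n_samples, params.fs, params.noise_exponent, params.noise_scale
        )
        band_rms = _band_rms(noise, params.fs)
        amp = params.burst_amp_snr * band_rms
        for ev in events:
            if ev["site"] != site:
                continue
            ev["amp"] = amp
            wf = burst_waveform(
                params.fs, ev["freq_hz"], ev["duration_ms"], amp, params.burst_amp_snr
            )
            c = int(round(ev["t_center_ms"] / 1000.0 * params.fs))
            a, b = c - len(wf) // 2, c - len(wf) // 2 + len(wf)
            if a < 0 or b > n_samples:
                ev["amp"] = np.nan  # fell off the edge; drop below
                continue
            noise[a:b] += wf
        data[si] = noise
        amps.append(amp)

    events = [e for e in events if np.isfinite(e.get("amp", np.nan))]

    # 4) map events to trials and build the truth log
    onsets = trials["onset_go_ms"].to_numpy()
    truth = pd.DataFrame(events)
    if len(truth):
        idx = np.searchsorted(onsets, truth["t_center_ms"].to_numpy(), side="right") - 1
        within = (idx >= 0) & (
            truth["t_center_ms"].to_numpy() - onsets[np.clip(idx, 0, None)]
            < TRIAL_LENGTH_MS
        )
        truth["trial_index"] = np.where(within, idx, -1)
        truth = truth.sort_values("t_center_ms").reset_index(drop=True)
    else:
        truth = pd.DataFrame(
            columns=[
                "site",
                "t_center_ms",
                "freq_hz",
                "duration_ms",
                "coupled",
                "amp",
                "trial_index",
            ]
        )

    ch = pd.DataFrame(
        {
            "name": list(params.sites),
            "site": list(params.sites),
            "hemisphere": ["left"] * len(params.sites),
            "contact": list(range(len(params.sites))),
        }
    )
    rec = LfpRecording(data=data, fs=params.fs, channels=ch)
    return rec, truth


def generate_fixture(
    config: dict | None = None, out_dir=None, seed: int | None = None
) -> dict:
    """Generate a full synthetic session (behavior + LFP + truth log).

    ``config`` may override any ``BehaviorGenParams`` / ``LfpGenParams``
    field under keys ``behavior`` and ``lfp``, plus ``coupling`` as a list of
    ``[source, target, lag_ms, probability]``.  When ``out_dir`` is given,
    writes ``lfp.h5``, ``events.tsv``, ``truth.tsv`` and the resolved config;
    outputs are byte-identical for identical (config, seed).
    """
    config = dict(config or {})
    beh_kwargs = dict(config.get("behavior", {}))
    lfp_kwargs = dict(config.get("lfp", {}))
    if seed is not None:
        beh_kwargs.setdefault("seed", int(seed))
        lfp_kwargs.setdefault("seed", int(seed) + 1)
    coupling = [CouplingRule(*c) for c in config.get("coupling", [])]
    if coupling:
        lfp_kwargs["coupling"] = coupling

    beh = BehaviorGenParams(**beh_kwargs)
    lfp = LfpGenParams(**lfp_kwargs)
    trials = simulate_behavior(beh)
    rec, truth = simulate_lfp(trials, lfp)

    out = {"trials": trials, "recording": rec, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_lfp_h5(rec, out_dir / "lfp.h5")
        save_events_tsv(trials, out_dir / "events.tsv")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
        resolved = {
            "behavior": {k: getattr(beh, k) for k in beh.__dataclass_fields__},
            "lfp": {
                k: getattr(lfp, k)
                for k in lfp.__dataclass_fields__
                if k not in ("rate_profiles", "coupling")
            },
            "coupling": [
                [c.source, c.target, c.lag_ms, c.probability] for c in coupling
            ],
        }
        with open(out_dir / "fixture_config.yaml", "w") as f:
            yaml.safe_dump(resolved, f, default_flow_style=False)
    return out
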