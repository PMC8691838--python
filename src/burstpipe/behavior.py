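"""Stop-signal-task behavioral scoring, exclusions, SSRT estimation, group tests.

SSRT is estimated with the integration method with go-omission replacement:
go omissions are replaced by the response deadline, go RTs are sorted
ascending, and SSRT = RT at rank ceil(N * p(respond | stop)) minus the mean
stop-signal delay.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as spstats

RESPONSE_DEADLINE_MS = 2000.0

OUTCOMES = ("correct-go", "wrong-go", "go-omission", "successful-stop", "failed-stop")


def score_trials(trials: pd.DataFrame, deadline_ms: float = RESPONSE_DEADLINE_MS) -> pd.DataFrame:
    """Assign outcomes from raw cue / press / RT fields.

    Go trials: correct press within the deadline -> correct-go; press of the
    wrong button -> wrong-go; no press -> go-omission.  Stop trials: any
    press -> failed-stop (a wrong-side press is still a failure to stop),
    none -> successful-stop.  An RT above the deadline must have been logged
    as an omission upstream and is rejected here.
    """
    out = trials.copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    if np.any(rt[np.isfinite(rt)] > deadline_ms):
        raise ValueError("RT beyond the response deadline: should be an omission")
    pressed = out["pressed"].fillna("").astype(str).to_numpy()
    responded = np.isfinite(rt) & (pressed != "")
    kinds = out["trial_kind"].to_numpy()
    hands = out["hand"].to_numpy()

    outcome = np.empty(len(out), dtype=object)
    is_go = kinds == "go"
    outcome[is_go & ~responded] = "go-omission"
    outcome[is_go & responded & (pressed == hands)] = "correct-go"
    outcome[is_go & responded & (pressed != hands)] = "wrong-go"
    outcome[~is_go & responded] = "failed-stop"
    outcome[~is_go & ~responded] = "successful-stop"
    out["outcome"] = outcome
    return out


def apply_exclusions(
    participants: dict[str, pd.DataFrame],
    block_go_accuracy_min: float = 0.60,
    participant_go_accuracy_min: float = 0.50,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Apply the block- and participant-level exclusion rules.

    A block is excluded if its go accuracy is below 60% or it contains no
    successful stop; a participant is excluded entirely if overall go
    accuracy is below chance (50%).  Returns the retained trial tables
    (excluded blocks dropped) and a report of every exclusion with its
    reason.
    """
    if not participants:
        raise ValueError("no participants supplied")
    kept: dict[str, pd.DataFrame] = {}
    report_rows = []
    for pid, trials in participants.items():
        go = trials[trials["trial_kind"] == "go"]
        overall_acc = (go["outcome"] == "correct-go").mean() if len(go) else np.nan
        if not (overall_acc >= participant_go_accuracy_min):
            report_rows.append(
                {
                    "participant": pid,
                    "block": -1,
                    "reason": f"participant go accuracy {overall_acc:.2f} < "
                    f"{participant_go_accuracy_min:.2f}",
                }
            )
            continue
        good_blocks = []
        for block, btr in trials.groupby("block"):
            bgo = btr[btr["trial_kind"] == "go"]
            acc = (bgo["outcome"] == "correct-go").mean() if len(bgo) else np.nan
            n_success = (btr["outcome"] == "successful-stop").sum()
            if not (acc >= block_go_accuracy_min):
                report_rows.append(
                    {
                        "participant": pid,
                        "block": block,
                        "reason": f"block go accuracy {acc:.2f} < "
                        f"{block_go_accuracy_min:.2f}",
                    }
                )
            elif n_success < 1:
                report_rows.append(
                    {
                        "participant": pid,
                        "block": block,
                        "reason": "no successful stop in block",
                    }
                )
            else:
                good_blocks.append(block)
        if good_blocks:
            kept[pid] = trials[trials["block"].isin(good_blocks)].reset_index(drop=True)
        else:
            report_rows.append(
                {"participant": pid, "block": -1, "reason": "all blocks excluded"}
            )
    report = pd.DataFrame(report_rows, columns=["participant", "block", "reason"])
    return kept, report


def compute_ssrt(
    go_rts_with_omissions,
    p_respond_given_stop: float,
    mean_ssd: float,
    deadline_ms: float = RESPONSE_DEADLINE_MS,
) -> float:
    """Integration-method SSRT with go-omission replacement.

    ``go_rts_with_omissions`` is a sequence of RTs in ms where omissions are
    NaN (or None); they are replaced by the deadline.  SSRT = sorted go RT at
    rank ceil(N * p) minus ``mean_ssd``.
    """
    rts = np.array(
        [deadline_ms if (r is None or not np.isfinite(r)) else float(r)
         for r in go_rts_with_omissions],
        dtype=float,
    )
    if rts.size == 0:
        raise ValueError("at least one go trial is required")
    if not 0 <= p_respond_given_stop <= 1:
        raise ValueError("p_respond_given_stop must lie in [0, 1]")
    if p_respond_given_stop == 0:
        raise ValueError("p(respond|stop)=0: integration-method SSRT undefined")
    rts.sort()
    rank = math.ceil(rts.size * p_respond_given_stop)  # 1-based
    return float(rts[rank - 1] - mean_ssd)


def participant_ssrt(trials: pd.DataFrame) -> dict:
    """SSRT and supporting behavioral metrics from a scored trial table.

    Both hands are pooled: one SSRT per participant, mean SSD pooled across
    hands.  Go RTs include wrong-side responses; omissions are replaced
    inside :func:`compute_ssrt`.
    """
    go = trials[trials["trial_kind"] == "go"]
    stop = trials[trials["trial_kind"] == "stop"]
    if len(stop) == 0:
        raise ValueError("no stop trials")
    p_respond = float((stop["outcome"] == "failed-stop").mean())
    mean_ssd = float(stop["ssd_ms"].mean())
    go_rts = [
        r if np.isfinite(r) else np.nan for r in go["rt_ms"].to_numpy(dtype=float)
    ]
    ssrt = (
        compute_ssrt(go_rts, p_respond, mean_ssd) if 0 < p_respond <= 1 else np.nan
    )
    failed = stop[stop["outcome"] == "failed-stop"]
    return {
        "go_accuracy": float((go["outcome"] == "correct-go").mean()),
        "stop_accuracy": float((stop["outcome"] == "successful-stop").mean()),
        "mean_go_rt": float(go["rt_ms"].mean()),
        "mean_failed_stop_rt": float(failed["rt_ms"].mean()) if len(failed) else np.nan,
        "mean_ssd": mean_ssd,
        "ssrt": ssrt,
        "n_blocks_included": int(trials["block"].nunique()),
    }


def split_matched_go(trials: pd.DataFrame) -> pd.DataFrame:
    """Label correct go trials fast/slow by a median split of go RT.

    RTs equal to the median go to the fast set.  Every matched go trial
    carries its staircase SSD as a virtual SSD so that go and stop trials can
    be compared over identical windows.  Returns the correct-go rows with
    added columns ``go_speed`` and ``virtual_ssd_ms``.
    """
    go = trials[trials["outcome"] == "correct-go"].copy()
    rts = go["rt_ms"].to_numpy(dtype=float)
    if len(go) < 2 or not np.any(np.isfinite(rts)):
        raise ValueError("need >= 2 correct go trials with RTs")
    med = np.median(rts)
    go["go_speed"] = np.where(rts <= med, "fast", "slow")
    go["virtual_ssd_ms"] = go["staircase_ssd_ms"]
    return go


def compare_groups(values_a, values_b) -> dict:
    """Two-sample pooled-variance t-test with Cohen's d.

    Used for comparing per-participant behavioral metrics between implant
    groups.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = spstats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    sp = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    d = 0.0 if sp == 0 else (a.mean() - b.mean()) / sp
    if sp == 0 and a.mean() == b.mean():
        t = 0.0
        p = 1.0
    return {"t": float(t), "df": int(df), "p": float(p), "cohen_d": float(d)}
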