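"""Permutation-based inference for burst rates and timing.

Observed F statistics come from the classical repeated-measures (or mixed)
ANOVA sums-of-squares decomposition; inference does not rely on parametric
F distributions (hence no sphericity correction) but on a permutation null:
condition labels are randomized within subject (and group labels across
subjects for the between factor), the F of each effect is recomputed
``n_perm`` times, and an observed effect is significant when it exceeds the
95th percentile of its null distribution AND its permutation p-value
(proportion of null F >= observed) is below .05.  Effect sizes are partial
eta squared = SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests


def rm_anova_f(data: np.ndarray) -> dict:
    """Two-way repeated-measures ANOVA F values and partial eta squared.

    ``data`` has shape (..., n_subjects, n_a, n_b); leading axes (e.g. a
    permutation axis) are carried through.  Returns per effect ('a', 'b',
    'ab'): F and eta2p arrays of the leading shape.
    """
    data = np.asarray(data, dtype=float)
    S, A, B = data.shape[-3:]
    if S < 2 or A < 2 or B < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    gm = data.mean(axis=(-3, -2, -1), keepdims=True)
    m_a = data.mean(axis=(-3, -1), keepdims=True)
    m_b = data.mean(axis=(-3, -2), keepdims=True)
    m_s = data.mean(axis=(-2, -1), keepdims=True)
    m_ab = data.mean(axis=-3, keepdims=True)
    m_as = data.mean(axis=-1, keepdims=True)
    m_bs = data.mean(axis=-2, keepdims=True)

    def ssum(x):
        return np.sum(x, axis=(-3, -2, -1))

    # keepdims means the mean arrays hold singleton axes; multiply by the
    # number of observations each deviation represents
    ss_a = S * B * ssum((m_a - gm) ** 2)
    ss_b = S * A * ssum((m_b - gm) ** 2)
    ss_ab = S * ssum((m_ab - m_a - m_b + gm) ** 2)
    ss_as = B * ssum((m_as - m_a - m_s + gm) ** 2)
    ss_bs = A * ssum((m_bs - m_b - m_s + gm) ** 2)
    resid = data - m_ab - m_as - m_bs + m_a + m_b + m_s - gm
    ss_abs = ssum(resid**2)

    # zero out floating-point dust so degenerate (constant) inputs give F = 0;
    # the floor is the squared rounding error of means at the data's scale
    scale = np.max(np.abs(data), axis=(-3, -2, -1))
    tol = S * A * B * (1e-13 * (scale + 1.0)) ** 2
    ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs = (
        np.where(ss < tol, 0.0, ss) for ss in (ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs)
    )

    df_a, df_b = A - 1, B - 1
    df_ab = df_a * df_b
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, ss_eff, ss_err, df_eff, df_err in (
            ("a", ss_a, ss_as, df_a, df_a * (S - 1)),
            ("b", ss_b, ss_bs, df_b, df_b * (S - 1)),
            ("ab", ss_ab, ss_abs, df_ab, df_ab * (S - 1)),
        ):
            f = (ss_eff / df_eff) / (ss_err / df_err)
            f = np.where(ss_err == 0, np.where(ss_eff == 0, 0.0, np.inf), f)
            eta = np.where(
                ss_eff + ss_err == 0, 0.0, ss_eff / (ss_eff + ss_err)
            )
            out[name] = {
                "F": f,
                "eta2p": eta,
                "df_effect": df_eff,
                "df_error": df_err,
            }
    return out


def perm_rm_anova(
    data: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    factor_names: tuple = ("a", "b"),
) -> pd.DataFrame:
    """Permutation two-way RM-ANOVA.

    ``data``: (n_subjects, n_a, n_b) cell means (e.g. subject x trial-type x
    time-bin burst rates).  The null randomizes the A x B cell labels within
    each subject.  Subjects with missing cells are dropped listwise.

    Returns a DataFrame with one row per effect: F, eta2p, p_perm,
    null_f_95, significant, n_perm, seed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, factor A levels, factor B levels)")
    complete = ~np.isnan(data).any(axis=(1, 2))
    if not complete.all():
        import warnings

        warnings.warn(f"dropping {int((~complete).sum())} subject(s) with missing cells")
    data = data[complete]
    S, A, B = data.shape
    if S < 3:
        raise ValueError("need >= 3 complete subjects")

    obs = rm_anova_f(data)
    rng = np.random.default_rng(seed)
    cells = data.reshape(S, A * B)
    idx = np.tile(np.arange(A * B), (n_perm, S, 1))
    idx = rng.permuted(idx, axis=2)
    perm = cells[np.arange(S)[None, :, None], idx].reshape(n_perm, S, A, B)
    null = rm_anova_f(perm)

    rows = []
    effect_labels = {
        "a": factor_names[0],
        "b": factor_names[1],
        "ab": f"{factor_names[0]} x {factor_names[1]}",
    }
    for key in ("a", "b", "ab"):
        f_obs = float(obs[key]["F"])
        f_null = null[key]["F"]
        p = float(np.mean(f_null >= f_obs))
        q95 = float(np.percentile(f_null, 95))
        rows.append(
            {
                "effect": effect_labels[key],
                "F": f_obs,
                "eta2_partial": float(obs[key]["eta2p"]),
                "df_effect": obs[key]["df_effect"],
                "df_error": obs[key]["df_error"],
                "p_perm": p,
                "null_f_95": q95,
                "significant": bool(f_obs > q95 and p < 0.05),
                "n_perm": n_perm,
                "n_subjects": S,
            }
        )
    return pd.DataFrame(rows)


def mixed_anova_f(values: np.ndarray, groups: np.ndarray) -> dict:
    """Mixed-design ANOVA F (between group, within factor, interaction).

    ``values``: (n_subjects, n_within) cell means; ``groups``: integer group
    label per subject.  Group sizes should be equal or near-equal (weighted-
    means solution).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    N, W = values.shape
    labels = np.unique(groups)
    G = labels.size
    if G < 2 or W < 2:
        raise ValueError("need >= 2 groups and >= 2 within levels")
    n_g = np.array([(groups == g).sum() for g in labels])
    if np.any(n_g < 2):
        raise ValueError("each group needs n >= 2 subjects")

    gm = values.mean()
    m_s = values.mean(axis=1)
    m_w = values.mean(axis=0)
    m_g = np.array([m_s[groups == g].mean() for g in labels])
    m_gw = np.vstack([values[groups == g].mean(axis=0) for g in labels])

    ss_total = ((values - gm) ** 2).sum()
    ss_between_subj = W * ((m_s - gm) ** 2).sum()
    ss_group = W * (n_g * (m_g - gm) ** 2).sum()
    ss_subj_in_group = ss_between_subj - ss_group
    ss_w = N * ((m_w - gm) ** 2).sum()
    ss_cells = (n_g[:, None] * (m_gw - gm) ** 2).sum()
    ss_gw = ss_cells - ss_group - ss_w
    ss_err_w = ss_total - ss_between_subj - ss_w - ss_gw

    df_g, df_w = G - 1, W - 1
    df_sg = N - G
    df_err = (N - G) * (W - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_g = (ss_group / df_g) / (ss_subj_in_group / df_sg)
        f_w = (ss_w / df_w) / (ss_err_w / df_err)
        f_gw = (ss_gw / (df_g * df_w)) / (ss_err_w / df_err)
    return {
        "between": {
            "F": float(np.nan_to_num(f_g, nan=0.0)),
            "eta2p": float(ss_group / (ss_group + ss_subj_in_group))
            if ss_group + ss_subj_in_group > 0
            else 0.0,
            "df": (df_g, df_sg),
        },
        "within": {
            "F": float(np.nan_to_num(f_w, nan=0.0)),
            "eta2p": float(ss_w / (ss_w + ss_err_w)) if ss_w + ss_err_w > 0 else 0.0,
            "df": (df_w, df_err),
        },
        "interaction": {
            "F": float(np.nan_to_num(f_gw, nan=0.0)),
            "eta2p": float(ss_gw / (ss_gw + ss_err_w)) if ss_gw + ss_err_w > 0 else 0.0,
            "df": (df_g * df_w, df_err),
        },
    }


def mixed_anova_burst_timing(
    values: np.ndarray,
    groups,
    n_perm: int = 10000,
    seed: int | None = None,
    within_name: str = "trial type",
    between_name: str = "subcortical location",
) -> pd.DataFrame:
    """Permutation mixed ANOVA on first-burst timing.

    ``values``: (n_subjects, n_within) mean latencies (e.g. successful- vs
    failed-stop); ``groups``: between-subjects label per subject (e.g. STN
    vs thalamus).  Null: group labels permuted across subjects and within-
    condition labels permuted within subject, jointly per permutation.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    obs = mixed_anova_f(values, groups)
    rng = np.random.default_rng(seed)
    N, W = values.shape
    null = {k: np.empty(n_perm) for k in ("between", "within", "interaction")}
    for p in range(n_perm):
        g_perm = rng.permutation(groups)
        v_perm = rng.permuted(values, axis=1)
        f = mixed_anova_f(v_perm, g_perm)
        for k in null:
            null[k][p] = f[k]["F"]
    rows = []
    labels = {
        "between": between_name,
        "within": within_name,
        "interaction": f"{between_name} x {within_name}",
    }
    for k in ("between", "within", "interaction"):
        f_obs = obs[k]["F"]
        pval = float(np.mean(null[k] >= f_obs))
        q95 = float(np.percentile(null[k], 95))
        rows.append(
            {
                "effect": labels[k],
                "F": f_obs,
                "eta2_partial": obs[k]["eta2p"],
                "df_effect": obs[k]["df"][0],
                "df_error": obs[k]["df"][1],
                "p_perm": pval,
                "null_f_95": q95,
                "significant": bool(f_obs > q95 and pval < 0.05),
                "n_perm": n_perm,
                "n_subjects": N,
            }
        )
    return pd.DataFrame(rows)


def holm_pairwise(contrasts: list[tuple]) -> pd.DataFrame:
    """Paired t-tests with Bonferroni-Holm correction over the family.

    ``contrasts`` is a list of ``(label, x, y)`` with x, y paired samples;
    contrasts with fewer than 2 pairs are skipped with a note.
    """
    rows = []
    for label, x, y in contrasts:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 2:
            rows.append({"contrast": label, "n": int(x.size), "t": np.nan, "p_raw": np.nan})
            continue
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = spstats.ttest_rel(x, y)
        rows.append({"contrast": label, "n": int(x.size), "t": float(t), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    tested = df["p_raw"].notna()
    adj = np.full(len(df), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            df.loc[tested, "p_raw"].to_numpy(), method="holm"
        )[1]
    df["p_holm"] = adj
    return df


def single_subject_burst_timing_test(latencies_a, latencies_b) -> dict:
    """One-sided two-sample t-test that site-A bursts occur earlier than
    site-B bursts, with trials as observations (single-subject analysis)."""
    a = np.asarray(latencies_a, dtype=float)
    b = np.asarray(latencies_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 latencies per site")
    t, p = spstats.ttest_ind(a, b, equal_var=True, alternative="less")
    return {"t": float(t), "p": float(p), "n_a": int(a.size), "n_b": int(b.size)}
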