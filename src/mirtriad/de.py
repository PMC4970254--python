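"""Per-probe fixed-effect differential expression between breeds.

The model is a one-way fixed-effect ANOVA on log2 intensities with breed as
the only factor (F = MS_between / MS_within, df = (g-1, n-g)); for two
balanced groups this is exactly the squared pooled t statistic.  An optional
additive categorical covariate (e.g. sex) is supported via a nested-model
F-test, with lsmeans evaluated at balanced covariate weights.  Multiple
testing is controlled with Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleTable


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q(i) = min_{j >= i} (m * p(j) / j) over the ascending-sorted p's, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_change(delta_log2: float, group_hi: str = "Duroc", group_lo: str = "PiNN"):
    """Linear fold change 2^|delta| with the direction reported separately."""
    d = float(delta_log2)
    if not np.isfinite(d):
        raise ValueError("delta_log2 must be finite")
    fc = 2.0 ** abs(d)
    if d > 0:
        return fc, f"up_in_{group_hi}"
    if d < 0:
        return fc, f"up_in_{group_lo}"
    return 1.0, "none"


def anova_fixed_effect(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    covariate: str | None = None,
    contrast: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """One-way fixed-effect ANOVA per probe; returns the per-probe DE table.

    Rows with missing values use complete samples only (n_used recorded).
    ``contrast`` fixes the (high, low) group order for delta_log2; by default
    ("Duroc", "PiNN") when present, otherwise sorted group names.
    """
    frame = samples.frame
    shared = [s for s in matrix.sample_ids if s in set(frame["sample_id"])]
    frame = frame.set_index("sample_id").loc[shared]
    groups = sorted(frame["breed"].unique())
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    counts = frame["breed"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    if contrast is None and len(groups) == 2:
        contrast = ("Duroc", "PiNN") if set(groups) == {"Duroc", "PiNN"} else (groups[0], groups[1])

    Y = matrix.values[shared].to_numpy(dtype=float)  # probes x samples
    breed = frame["breed"].to_numpy()
    member = {g: breed == g for g in groups}

    if covariate is None:
        means, F, p, n_used = _oneway_f(Y, member)
    else:
        if covariate not in frame.columns:
            raise KeyError(f"covariate {covariate!r} not in sample table")
        means, F, p, n_used = _covariate_f(Y, member, frame[covariate].to_numpy())

    out = pd.DataFrame(index=pd.Index(matrix.probe_ids, name="probe_id"))
    for g in groups:
        out[f"lsmean_{g}"] = means[g]
    out["n_used"] = n_used
    if len(groups) == 2 and contrast is not None:
        hi, lo = contrast
        delta = means[hi] - means[lo]
        out["delta_log2"] = delta
        out["fold_change"] = 2.0 ** np.abs(delta)
        direction = np.where(delta > 0, f"up_in_{hi}", np.where(delta < 0, f"up_in_{lo}", "none"))
        out["direction"] = direction
    out["F"] = F
    out["p"] = p
    out["q"] = bh_fdr(p)
    return out


def _oneway_f(Y: np.ndarray, member: dict[str, np.ndarray]):
    """Vectorized one-way ANOVA over probe rows with NaN-aware group means."""
    groups = list(member)
    n_g = {}
    means = {}
    valid = ~np.isnan(Y)
    for g in groups:
        cols = member[g]
        n_g[g] = valid[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore"):
            means[g] = np.nansum(Y[:, cols], axis=1) / np.maximum(n_g[g], 1)
        means[g] = np.where(n_g[g] > 0, means[g], np.nan)
    n_tot = sum(n_g.values())
    grand = sum(means[g] * n_g[g] for g in groups) / n_tot
    ss_between = sum(n_g[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = np.zeros(Y.shape[0])
    for g in groups:
        cols = member[g]
        dev = Y[:, cols] - means[g][:, None]
        ss_within += np.nansum(dev**2, axis=1)
    df_b = len(groups) - 1
    df_w = n_tot - len(groups)
    ms_b = ss_between / df_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_w = ss_within / df_w
        F = ms_b / ms_w
    # degenerate rows: no spread at all -> F = 0, p = 1; spread only between -> p = 0
    zero_w = ms_w <= 0
    F = np.where(zero_w & (ms_b <= 0), 0.0, F)
    F = np.where(zero_w & (ms_b > 0), np.inf, F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df_b, df_w))
    p = np.where(F == 0.0, 1.0, p)
    return means, F, p, n_tot


def _covariate_f(Y: np.ndarray, member: dict[str, np.ndarray], cov: np.ndarray):
    """F-test for the group factor adjusting for an additive categorical covariate."""
    groups = list(member)
    n = Y.shape[1]
    levels = sorted(pd.unique(cov))
    X_cov = np.column_stack(
        [np.ones(n)] + [(cov == lv).astype(float) for lv in levels[1:]]
    )
    X_full = np.column_stack(
        [X_cov] + [member[g].astype(float) for g in groups[1:]]
    )
    rss_f, rank_f = _rss(X_full, Y)
    rss_r, rank_r = _rss(X_cov, Y)
    df_num = rank_f - rank_r
    df_den = n - rank_f
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    F = np.where((rss_f <= 1e-12) & (rss_r - rss_f <= 1e-12), 0.0, F)
    F = np.where((rss_f <= 1e-12) & (rss_r - rss_f > 1e-12), np.inf, F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df_num, df_den))
    p = np.where(F == 0.0, 1.0, p)
    # lsmeans: predictions per group at balanced covariate weights
    beta, _, _, _ = np.linalg.lstsq(X_full, Y.T, rcond=None)
    means = {}
    k_cov = X_cov.shape[1]
    for gi, g in enumerate(groups):
        x = np.zeros(X_full.shape[1])
        x[0] = 1.0
        x[1:k_cov] = 1.0 / len(levels)  # balanced over covariate levels
        if gi > 0:
            x[k_cov + gi - 1] = 1.0
        means[g] = x @ beta
    return means, F, p, np.full(Y.shape[0], n)


def _rss(X: np.ndarray, Y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return (resid**2).sum(axis=0), rank


@dataclass
class DESelection:
    """Probes passing p < p_threshold and q < q_threshold (strict)."""

    probe_ids: list[str]
    p_threshold: float
    q_threshold: float
    directions: dict[str, str] = field(default_factory=dict)


def select_de(result: pd.DataFrame, p_threshold: float = 0.05, q_threshold: float = 0.2) -> DESelection:
    mask = (result["p"] < p_threshold) & (result["q"] < q_threshold)
    ids = list(result.index[mask])
    directions = (
        dict(zip(ids, result.loc[ids, "direction"])) if "direction" in result.columns else {}
    )
    return DESelection(ids, p_threshold, q_threshold, directions)


def collapse_to_mature(selection: DESelection, annotations: pd.DataFrame) -> dict:
    """Summarize a probe-level selection at the mature-miRNA level.

    Returns the distinct mature names, per-direction unique-mature counts, and
    the matures whose probes disagree on direction (flagged, counted nowhere).
    """
    annot = annotations.set_index("probe_id")["mature_name"]
    missing = [p for p in selection.probe_ids if p not in annot.index]
    if missing:
        raise KeyError(f"probes without annotation: {missing[:5]}")
    by_mature: dict[str, set[str]] = {}
    for probe in selection.probe_ids:
        direction = selection.directions.get(probe, "none")
        by_mature.setdefault(annot[probe], set()).add(direction)
    inconsistent = sorted(m for m, dirs in by_mature.items() if len(dirs) > 1)
    per_direction: dict[str, int] = {}
    for mature, dirs in by_mature.items():
        if len(dirs) == 1:
            d = next(iter(dirs))
            per_direction[d] = per_direction.get(d, 0) + 1
    return {
        "n_probes": len(selection.probe_ids),
        "n_unique_mature": len(by_mature),
        "per_direction": per_direction,
        "inconsistent": inconsistent,
    }
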