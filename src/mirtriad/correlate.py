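"""Pairwise Pearson correlation with t-transform p-values and BH-FDR.

Used for every correlation family in the pipeline: miRNA x mRNA expression,
molecule x phenotype, gene x gene (cross-list matrices) and qPCR/chip
platform concordance.  Missing values are handled pairwise-complete and the
per-pair n is recorded; p-values come from t = r*sqrt(n-2)/sqrt(1-r^2) with
n-2 degrees of freedom (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr
from .io import ExpressionMatrix


def pearson_r(x, y) -> tuple[float, int]:
    """Product-moment correlation on pairwise-complete observations.

    Returns (r, n_used); r is NaN for a constant vector (undefined
    correlation — callers exclude and log such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, got {n}")
    xv, yv = x[mask], y[mask]
    xd = xv - xv.mean()
    yd = yv - yv.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan"), n
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    return r, n


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t-transform, df = n-2)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _pvalues_vec(r: np.ndarray, n) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (t, p) for arrays of r (NaN passes through)."""
    r = np.asarray(r, dtype=float)
    n = np.broadcast_to(np.asarray(n), r.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return t, p


def correlate_all(
    mat_a: ExpressionMatrix, mat_b: ExpressionMatrix, family_fdr: bool = True
) -> pd.DataFrame:
    """All rows(A) x rows(B) Pearson correlations over the shared samples.

    Returns a tidy frame (id_a, id_b, n, r, t, p[, q]); q is BH over the
    whole family.  Constant rows yield NaN r/p and are excluded from the BH
    family but kept in the output for accounting.
    """
    shared = [s for s in mat_a.sample_ids if s in set(mat_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    A = mat_a.values[shared].to_numpy(dtype=float)
    B = mat_b.values[shared].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        R, N = _pairwise_complete_corr(A, B)
    else:
        n = len(shared)
        R = _fast_corr(A, B)
        N = np.full_like(R, n)
    t, p = _pvalues_vec(R, N)
    ia, ib = np.meshgrid(np.arange(A.shape[0]), np.arange(B.shape[0]), indexing="ij")
    out = pd.DataFrame(
        {
            "id_a": np.asarray(mat_a.probe_ids, dtype=object)[ia.ravel()],
            "id_b": np.asarray(mat_b.probe_ids, dtype=object)[ib.ravel()],
            "n": N.ravel().astype(int),
            "r": R.ravel(),
            "t": t.ravel(),
            "p": p.ravel(),
        }
    )
    if family_fdr:
        out["q"] = np.nan
        defined = out["p"].notna()
        if defined.any():
            out.loc[defined, "q"] = bh_fdr(out.loc[defined, "p"].to_numpy())
    return out


def _fast_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n = A.shape[1]
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Az**2).sum(axis=1))
    sb = np.sqrt((Bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Az @ Bz.T) / np.outer(sa, sb)
    R[:, sb == 0] = np.nan
    R[sa == 0, :] = np.nan
    return np.clip(R, -1.0, 1.0, out=R)


def _pairwise_complete_corr(A: np.ndarray, B: np.ndarray):
    R = np.empty((A.shape[0], B.shape[0]))
    N = np.empty_like(R, dtype=int)
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            try:
                r, n = pearson_r(A[i], B[j])
            except ValueError:
                r, n = np.nan, int((np.isfinite(A[i]) & np.isfinite(B[j])).sum())
            R[i, j], N[i, j] = r, n
    return R, N


def correlate_with_phenotypes(
    mat: ExpressionMatrix, phenotypes: pd.DataFrame, p_threshold: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One CorrResult per (probe, trait), plus a per-probe significance summary.

    ``phenotypes``: traits x samples.  Both correlation signs are retained.
    The summary flags probes correlated (p < p_threshold) with >= 1 trait.
    """
    pheno = ExpressionMatrix(phenotypes[[c for c in phenotypes.columns if c in set(mat.sample_ids)]])
    results = correlate_all(mat, pheno, family_fdr=False)
    results = results.rename(columns={"id_a": "probe_id", "id_b": "trait"})
    sig = results[results["p"] < p_threshold]
    n_sig = sig.groupby("probe_id").size()
    summary = pd.DataFrame(index=pd.Index(mat.probe_ids, name="probe_id"))
    summary["n_significant_traits"] = n_sig.reindex(summary.index).fillna(0).astype(int)
    summary["any_significant"] = summary["n_significant_traits"] > 0
    return results, summary


# ---------------------------------------------------------------------------
# qPCR concordance
# ---------------------------------------------------------------------------

@dataclass
class QpcrRecord:
    """One qPCR measurement normalized to the 5S/U6 reference pair.

    delta_ct uses the arithmetic mean of the two reference Ct values, which
    equals normalizing to the geometric mean of the linear-scale reference
    levels; rel_expr = 2^(-delta_ct).
    """

    sample_id: str
    ct_target: float
    ct_ref_5S: float
    ct_ref_U6: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - 0.5 * (self.ct_ref_5S + self.ct_ref_U6)

    @property
    def rel_expr(self) -> float:
        return float(2.0 ** (-self.delta_ct))


def qpcr_concordance(qpcr: pd.DataFrame, chip: ExpressionMatrix) -> pd.DataFrame:
    """Per-miRNA Pearson r between qPCR 2^-dCt and chip log2 signal.

    ``qpcr`` columns: mirna_id, sample_id, ct_target, ct_ref_5S, ct_ref_U6.
    """
    rows = []
    for mirna_id, sub in qpcr.groupby("mirna_id", sort=True):
        if mirna_id not in set(chip.probe_ids):
            raise KeyError(f"miRNA {mirna_id!r} not on the chip matrix")
        rel = {
            row.sample_id: QpcrRecord(
                row.sample_id, row.ct_target, row.ct_ref_5S, row.ct_ref_U6
            ).rel_expr
            for row in sub.itertuples(index=False)
        }
        samples = [s for s in chip.sample_ids if s in rel]
        if len(samples) < 3:
            raise ValueError(f"{mirna_id}: need >= 3 matched samples, got {len(samples)}")
        x = np.array([rel[s] for s in samples])
        y = chip.values.loc[mirna_id, samples].to_numpy(dtype=float)
        r, n = pearson_r(x, y)
        rows.append({"mirna_id": mirna_id, "n": n, "r": r, "p": pearson_pvalue(r, n)})
    return pd.DataFrame(rows, columns=["mirna_id", "n", "r", "p"])
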