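"""Weighted multiple-testing procedures.

Given p-values :math:`P_1,\\dots,P_m` and mean-one weights
:math:`W_1,\\dots,W_m` (:math:`\\sum W_i = m`), define the weighted p-value
:math:`Q_i = P_i / W_i` (not itself a p-value; it may exceed 1).  The
procedures below apply the classical Bonferroni, Holm and
Benjamini-Hochberg thresholds to the :math:`Q_i` and reduce exactly to the
classical procedures under unit weights:

* weighted Bonferroni (FWER): reject every :math:`H_j` with
  :math:`Q_j \\le \\alpha/m`;
* weighted Holm (FWER, step-down): with :math:`Q_{(1)} \\le \\dots \\le Q_{(m)}`
  and the weights in the matching order, reject the ``j`` smallest where
  ``j`` is the largest index such that
  :math:`Q_{(i)} \\le \\alpha / \\sum_{k \\ge i} W_{(k)}` for all ``i <= j``;
* weighted Benjamini-Hochberg (FDR, step-up): largest ``j`` with
  :math:`Q_{(j)} \\le \\alpha j / m`.

An *effective test count* ``m_eff = m * ratio`` (correlation-adjusted number
of independent SNPs) may replace ``m`` in every threshold; inside Holm the
weight-sum denominators are rescaled by ``m_eff / m`` so the first step
reproduces ``alpha / m_eff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AssocTable
from .weights import WeightVector

__all__ = [
    "QTable",
    "RejectionReport",
    "weighted_pvalues",
    "effective_test_count",
    "weighted_bonferroni",
    "weighted_holm",
    "weighted_bh",
    "rank_shift_table",
    "qq_table",
]


def _competition_rank(values: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
    """1-based ranks ascending in ``values``, ties broken by ``tiebreak``."""
    order = np.lexsort((tiebreak, values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


@dataclass
class QTable:
    """Weighted p-values aligned with an association table.

    Rows where the scan failed to produce a p-value carry ``q = inf`` so they
    can never be rejected.
    """

    df: pd.DataFrame  # snp_id, p, w, q, rank_p, rank_q

    @property
    def m(self) -> int:
        return len(self.df)

    @property
    def q(self) -> np.ndarray:
        return self.df["q"].to_numpy(dtype=float)

    @property
    def w(self) -> np.ndarray:
        return self.df["w"].to_numpy(dtype=float)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()


def weighted_pvalues(assoc: AssocTable, wv: WeightVector) -> QTable:
    """Form Q_i = P_i / W_i, verifying id-level alignment first."""
    if not wv.normalized:
        raise ValueError("weights must be normalized to mean one before weighting p-values")
    ids_a = assoc.snp_ids
    ids_w = wv.snp_ids
    if len(ids_a) != len(ids_w) or (ids_a != ids_w).any():
        bad = (
            int(np.flatnonzero(ids_a[: len(ids_w)] != ids_w[: len(ids_a)])[0])
            if len(ids_a) == len(ids_w)
            else 0
        )
        raise ValueError(
            f"association table and weight vector are misaligned "
            f"(first mismatch: {ids_a[bad]!r} vs {ids_w[bad]!r})"
        )
    p = assoc.p
    with np.errstate(invalid="ignore"):
        q = np.where(np.isnan(p), np.inf, p / wv.w)
    df = pd.DataFrame({"snp_id": ids_a, "p": p, "w": wv.w, "q": q})
    df["rank_p"] = _competition_rank(np.where(np.isnan(p), np.inf, p), ids_a)
    df["rank_q"] = _competition_rank(q, ids_a)
    df["q_exceeds_one"] = q > 1.0
    return QTable(df)


def effective_test_count(m: int, ratio: float) -> float:
    """Correlation-adjusted number of independent tests, ``m * ratio`` (not rounded)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < ratio <= 1:
        raise ValueError(f"effective ratio must lie in (0, 1], got {ratio}")
    return m * ratio


@dataclass
class RejectionReport:
    """Decisions of one procedure at one level: per-SNP reject flag and threshold."""

    procedure: str
    alpha: float
    count: float  # m or the effective test count actually used
    table: pd.DataFrame  # snp_id, q, threshold, reject

    @property
    def rejected(self) -> list[str]:
        sub = self.table[self.table["reject"]]
        sub = sub.sort_values(["q", "snp_id"], kind="mergesort")
        return list(sub["snp_id"])

    @property
    def n_rejected(self) -> int:
        return int(self.table["reject"].sum())


# -- array cores (shared with the permutation size study) ---------------------

def bonferroni_mask(q: np.ndarray, alpha: float, count: float) -> np.ndarray:
    return q <= alpha / count


def holm_mask(q: np.ndarray, w: np.ndarray, alpha: float, count: float | None = None) -> np.ndarray:
    """Step-down rejection mask; thresholds alpha / suffix-sum of sorted weights,
    rescaled by count/m when an effective count is supplied."""
    m = len(q)
    order = np.lexsort((np.arange(m), q))
    qs = q[order]
    ws = w[order]
    denom = np.cumsum(ws[::-1])[::-1]  # sum_{k >= i} W_(k)
    if count is not None:
        denom = denom * (count / m)
    ok = qs <= alpha / denom
    mask = np.zeros(m, dtype=bool)
    if not ok[0]:
        return mask
    first_fail = np.argmin(ok) if not ok.all() else m
    mask[order[:first_fail]] = True
    return mask


def bh_mask(q: np.ndarray, alpha: float, count: float) -> np.ndarray:
    m = len(q)
    order = np.lexsort((np.arange(m), q))
    qs = q[order]
    thr = alpha * np.arange(1, m + 1) / count
    passing = np.flatnonzero(qs <= thr)
    mask = np.zeros(m, dtype=bool)
    if len(passing):
        j = passing[-1] + 1
        mask[order[:j]] = True
    return mask


# -- report-level procedures --------------------------------------------------

def _report(name: str, qt: QTable, mask: np.ndarray, thresholds: np.ndarray,
            alpha: float, count: float) -> RejectionReport:
    table = pd.DataFrame(
        {
            "snp_id": qt.snp_ids,
            "p": qt.df["p"].to_numpy(),
            "w": qt.w,
            "q": qt.q,
            "threshold": thresholds,
            "reject": mask,
        }
    )
    return RejectionReport(procedure=name, alpha=alpha, count=count, table=table)


def weighted_bonferroni(qt: QTable, alpha: float, count: float | None = None) -> RejectionReport:
    """Single-step FWER control: reject where Q_i <= alpha / count."""
    count = float(count if count is not None else qt.m)
    if count <= 0:
        raise ValueError("test count must be positive")
    thr = alpha / count
    mask = bonferroni_mask(qt.q, alpha, count)
    return _report("weighted_bonferroni", qt, mask, np.full(qt.m, thr), alpha, count)


def weighted_holm(
    assoc: AssocTable,
    wv: WeightVector,
    alpha: float,
    count: float | None = None,
) -> RejectionReport:
    """Step-down FWER control with weight-sum denominators."""
    qt = weighted_pvalues(assoc, wv)
    m = qt.m
    used = float(count if count is not None else m)
    order = np.lexsort((np.arange(m), qt.q))
    denom = np.cumsum(wv.w[order][::-1])[::-1]
    if count is not None:
        denom = denom * (used / m)
    thr_sorted = alpha / denom
    thresholds = np.empty(m)
    thresholds[order] = thr_sorted
    mask = holm_mask(qt.q, wv.w, alpha, count)
    return _report("weighted_holm", qt, mask, thresholds, alpha, used)


def weighted_bh(qt: QTable, alpha: float, count: float | None = None) -> RejectionReport:
    """Step-up FDR control: largest j with Q_(j) <= alpha * j / count."""
    count = float(count if count is not None else qt.m)
    if count <= 0:
        raise ValueError("test count must be positive")
    m = qt.m
    order = np.lexsort((np.arange(m), qt.q))
    thresholds = np.empty(m)
    thresholds[order] = alpha * np.arange(1, m + 1) / count
    mask = bh_mask(qt.q, alpha, count)
    return _report("weighted_bh", qt, mask, thresholds, alpha, count)


def rank_shift_table(
    assoc: AssocTable,
    qt: QTable,
    eqtl_flags: np.ndarray | None = None,
) -> pd.DataFrame:
    """Plot-ready comparison of p-value ranks before and after weighting.

    Ranks are 1-based, ascending, ties broken by snp_id.  ``rank_shift`` is
    positive when weighting improved (lowered) a SNP's rank.
    """
    out = qt.df[["snp_id", "p", "q", "rank_p", "rank_q"]].copy()
    out["is_eqtl"] = (
        np.asarray(eqtl_flags, dtype=bool)
        if eqtl_flags is not None
        else qt.w > 1.0
    )
    out["rank_shift"] = out["rank_p"] - out["rank_q"]
    return out


def qq_table(qt: QTable) -> pd.DataFrame:
    """Sorted observed vs expected -log10 p (and weighted q), for Q-Q displays.

    Expected quantiles use the (i - 0.5)/m plotting positions.
    """
    m = qt.m
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    p_sorted = np.sort(qt.df["p"].to_numpy(dtype=float))
    q_sorted = np.sort(qt.q)
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "expected_neglog10": expected,
                "observed_neglog10_p": -np.log10(p_sorted),
                "observed_neglog10_q": -np.log10(q_sorted),
            }
        )
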