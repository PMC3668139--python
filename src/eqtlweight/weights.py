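"""eQTL-derived hypothesis weights.

Two schemes, both normalized to mean one (the condition under which the
weighted procedures keep their FWER/FDR guarantees):

* **general weight** -- :math:`w_g = \\sqrt{-\\log_{10} p_{\\mathrm{eQTL}}}`
  for a SNP with eQTL evidence, 1 otherwise.  The square root tempers the
  up-weighting of the very strongest eQTLs.  Raw general weights for eQTL
  SNPs are floored at 1 so that weak eQTL evidence (p_eQTL > 0.1, which a
  LOD-thresholded reference cannot produce but synthetic inputs can) never
  down-weights a SNP before normalization.
* **binary weight** -- a two-valued weight: up-weight ``B`` for the eQTL
  fraction ``epsilon`` of hypotheses, down-weight ``b`` for the rest, with
  the mean-one constraint ``eps*B + (1-eps)*b = 1``.  The optimal ``B``
  under a one-sided normal power model is available from
  :func:`solve_binary_upweight`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .io import AssocTable, EqtlTable

__all__ = [
    "WeightVector",
    "BinaryWeightParams",
    "general_weights",
    "binary_weights",
    "normalize_weights",
    "solve_binary_upweight",
    "MAGICS_BINARY_PRESET",
]

_MEAN_TOL = 1e-12


@dataclass
class WeightVector:
    """Per-SNP positive weights aligned index-for-index with an AssocTable."""

    snp_ids: np.ndarray
    w: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != self.snp_ids.shape:
            raise ValueError("weights and snp_ids must be aligned")
        if not (self.w > 0).all():
            raise ValueError("all weights must be strictly positive")
        if self.normalized and abs(self.w.mean() - 1.0) > 1e-9:
            raise ValueError("weight vector flagged normalized but mean != 1")

    @property
    def m(self) -> int:
        return len(self.w)

    def normalize(self) -> "WeightVector":
        return normalize_weights(self)

    def __len__(self) -> int:
        return self.m


@dataclass(frozen=True)
class BinaryWeightParams:
    """Parameters of the two-valued weight: fraction ``epsilon`` of hypotheses
    receives up-weight ``B``, the rest down-weight ``b``; ``eps*B + (1-eps)*b = 1``."""

    epsilon: float
    B: float
    b: float
    alpha: float | None = None
    beta: float | None = None
    m: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.b <= 0:
            raise ValueError("down-weight b must be positive")
        if not (self.B >= 1 >= self.b):
            raise ValueError(f"need B >= 1 >= b, got B={self.B}, b={self.b}")
        mean = self.epsilon * self.B + (1 - self.epsilon) * self.b
        if abs(mean - 1.0) > 1e-6:
            raise ValueError(
                f"mean-one constraint violated: eps*B + (1-eps)*b = {mean:.8f}"
            )

    @classmethod
    def from_up_weight(
        cls,
        epsilon: float,
        B: float,
        alpha: float | None = None,
        beta: float | None = None,
        m: int | None = None,
    ) -> "BinaryWeightParams":
        """Closed-form down-weight from the mean-one constraint:
        ``b = (1 - eps*B) / (1 - eps)``."""
        if epsilon * B >= 1:
            raise ValueError(f"infeasible: eps*B = {epsilon * B:.4f} >= 1 leaves b <= 0")
        b = (1.0 - epsilon * B) / (1.0 - epsilon)
        return cls(epsilon=epsilon, B=B, b=b, alpha=alpha, beta=beta, m=m)


#: Reference preset: eQTL fraction 10.6% of ~300k GWAS SNPs at FWER 0.05 and
#: target power 60% gives up-weight 3.70 / down-weight 0.68.
MAGICS_BINARY_PRESET = BinaryWeightParams.from_up_weight(
    epsilon=0.106, B=3.70, alpha=0.05, beta=0.4, m=300_821
)


def general_weights(assoc: AssocTable, eqtl: EqtlTable) -> WeightVector:
    """Raw (unnormalized) general weights: ``sqrt(-log10 p_eqtl)`` for SNPs in
    the eQTL table (floored at 1), and 1 for all other SNPs."""
    pmap = eqtl.p_eqtl_map()
    w = np.ones(assoc.m, dtype=float)
    for i, sid in enumerate(assoc.snp_ids):
        p_eqtl = pmap.get(sid)
        if p_eqtl is None:
            continue
        if p_eqtl >= 1.0:
            raise ValueError(f"eQTL p-value >= 1 for {sid!r} gives a non-positive weight")
        w[i] = max(1.0, np.sqrt(-np.log10(p_eqtl)))
    return WeightVector(assoc.snp_ids.copy(), w, normalized=False)


def binary_weights(
    assoc: AssocTable,
    eqtl_flags: np.ndarray,
    params: BinaryWeightParams,
    renormalize: bool = True,
) -> WeightVector:
    """Two-valued weights: ``params.B`` for flagged SNPs, ``params.b`` otherwise.

    The mean-one constraint holds exactly only when the realized flag fraction
    equals ``params.epsilon``; otherwise the vector is renormalized (with a
    warning) when ``renormalize`` is set, or returned raw.
    """
    flags = np.asarray(eqtl_flags, dtype=bool)
    if flags.shape != (assoc.m,):
        raise ValueError("eqtl_flags must align with the association table")
    w = np.where(flags, params.B, params.b)
    realized = flags.mean()
    mean = w.mean()
    if abs(mean - 1.0) <= 1e-9:
        return WeightVector(assoc.snp_ids.copy(), w, normalized=True)
    if renormalize:
        if flags.all() or not flags.any():
            warnings.warn(
                "eQTL flags are constant; binary weights renormalize to unit weights",
                stacklevel=2,
            )
        else:
            warnings.warn(
                f"realized eQTL fraction {realized:.4f} != epsilon {params.epsilon}; "
                "renormalizing weights to mean one",
                stacklevel=2,
            )
        return WeightVector(assoc.snp_ids.copy(), w / mean, normalized=True)
    return WeightVector(assoc.snp_ids.copy(), w, normalized=False)


def normalize_weights(wv: WeightVector) -> WeightVector:
    """Divide by the mean so that ``mean(w) = 1`` (and ``sum(w) = m``).

    Idempotent, order-preserving, and invariant to positive rescaling of the
    raw weights.
    """
    if not (wv.w > 0).all():
        raise ValueError("cannot normalize: non-positive weight present")
    w = wv.w / wv.w.mean()
    # second pass kills the last-ulp drift so the mean-one invariant is tight
    w = w / w.mean()
    return WeightVector(wv.snp_ids.copy(), w, normalized=True)


def solve_binary_upweight(
    epsilon: float,
    alpha: float,
    beta: float,
    m: int,
    xi: float | None = None,
) -> BinaryWeightParams:
    """Optimal binary up-weight under a one-sided normal power model.

    Each test rejects when its z-statistic exceeds the one-sided critical
    value of a level ``alpha * w / m`` test.  The reference effect size
    ``xi`` defaults to the effect detected with 50% power by the unweighted
    Bonferroni threshold, ``xi = Phi^{-1}(1 - alpha/m)``.  The up-weight is
    the smallest ``B`` that gives the favored fraction ``epsilon`` of
    hypotheses power ``1 - beta`` at ``xi``:

    .. math:: B = (m / \\alpha) \\, \\bar\\Phi(\\xi + \\Phi^{-1}(\\beta)),

    capped by feasibility ``eps * B < 1``; the down-weight follows from the
    mean-one constraint.  With these defaults the parameters
    ``(eps=0.106, alpha=0.05, beta=0.4, m=300821)`` give ``B = 3.70``.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    if not 0 < alpha < 1 or not 0 < beta < 1:
        raise ValueError("alpha and beta must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    if xi is None:
        xi = norm.isf(alpha / m)
    B = (m / alpha) * norm.sf(xi + norm.ppf(beta))
    B = max(1.0, B)
    if epsilon * B >= 1:
        raise ValueError(
            f"infeasible: required up-weight B = {B:.3f} violates eps*B < 1 "
            f"for eps = {epsilon}"
        )
    return BinaryWeightParams.from_up_weight(epsilon, B, alpha=alpha, beta=beta, m=m)
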