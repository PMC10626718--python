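"""Iterative expression-conservation (EC) scoring of ortholog pairs.

Two species rarely share a tissue panel, so their expression matrices cannot
be compared column-wise. EC instead compares each species' *internal*
correlation structure: align n ortholog pairs as rows of a species-A and a
species-B expression matrix, convert each to an n x n Pearson correlation
matrix (R^A, R^B), and score pair i by correlating row i of R^A with row i
of R^B — "do these two genes correlate with the other ortholog pairs in the
same way in both species?".

The initial estimate EC_0(i) uses all partner positions equally. Each
subsequent iteration focuses the comparison on pairs that already look
conserved: EC_k(i) is a *weighted* Pearson correlation over the positions
g' = { l != i : EC_{k-1}(l) > 0 }, with weights w_l = EC_{k-1}(l) (pairs with
non-positive EC are excluded from the weighting). Iteration stops when
sum_i (EC_k(i) - EC_{k-1}(i))^2 < 0.1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedExpression",
    "ECResult",
    "MannWhitneySummary",
    "correlation_matrix",
    "ec_initial",
    "weighted_pcc",
    "run_until_converged",
    "ec_iterate",
    "compare_ec_distributions",
    "ec_quantile_placement",
    "ec_from_paired",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedExpression:
    """Row-aligned expression of n ortholog pairs in two species.

    Row i of ``matrix_a`` is the species-A gene of pair i and row i of
    ``matrix_b`` its species-B partner; the condition panels (columns) of the
    two species are independent and need not match in number or kind —
    that mismatch is exactly what the EC statistic is built to handle.
    """

    pairs: pd.DataFrame  # columns gene_a, gene_b
    matrix_a: pd.DataFrame
    matrix_b: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.pairs)
        if len(self.matrix_a) != n or len(self.matrix_b) != n:
            raise ValueError("matrices must have one row per ortholog pair")
        if n < 4:
            raise ValueError(f"need at least 4 ortholog pairs, got {n}")
        if list(self.matrix_a.index) != list(self.pairs["gene_a"]):
            raise ValueError("matrix_a rows not aligned with pair order")
        if list(self.matrix_b.index) != list(self.pairs["gene_b"]):
            raise ValueError("matrix_b rows not aligned with pair order")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class ECResult:
    """Per-pair EC scores across iterations.

    ``ec`` is the final vector (NaN for pairs dropped as degenerate);
    ``trace[k]`` is the EC vector after iteration k (trace[0] = EC_0);
    ``delta_history[k-1]`` is sum_i (trace[k][i] - trace[k-1][i])^2.
    """

    ec: np.ndarray
    trace: list[np.ndarray]
    delta_history: list[float]
    converged: bool
    tolerance: float

    @property
    def ec_initial(self) -> np.ndarray:
        return self.trace[0]

    @property
    def n_iterations(self) -> int:
        return len(self.trace) - 1


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between the rows of a gene x condition array.

    Symmetric with unit diagonal. Raises if any row has zero variance
    (such genes must be dropped upstream) or fewer than 3 conditions.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("need a 2-D array with at least 3 conditions")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance expression rows (drop upstream): {bad}")
    r = np.corrcoef(values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def _check_square_pair(Ra: np.ndarray, Rb: np.ndarray, min_n: int = 4) -> int:
    Ra = np.asarray(Ra, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    if Ra.shape != Rb.shape or Ra.ndim != 2 or Ra.shape[0] != Ra.shape[1]:
        raise ValueError("correlation matrices must be square with equal shape")
    n = Ra.shape[0]
    if n < min_n:
        raise ValueError(f"need at least {min_n} ortholog pairs, got {n}")
    return n


def ec_initial(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """EC_0(i): Pearson correlation of row i of Ra with row i of Rb.

    The self position i is excluded from both rows (it is 1 in both matrices
    and would inflate every score by a constant artifact), so the correlation
    runs over the n-1 off-diagonal positions. A row whose off-diagonal
    entries have zero variance in either matrix yields NaN: that pair is
    flagged and excluded from later weighting.
    """
    n = _check_square_pair(Ra, Rb)
    Ra = np.asarray(Ra, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    ec = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ec[i] = _pearson_or_nan(Ra[i, mask], Rb[i, mask])
    return ec


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if den == 0:
        return math.nan
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def weighted_pcc(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with weighted means and a symmetric denominator.

    PCCw(x, y; w) = sum w (x - xbar)(y - ybar)
                    / sqrt(sum w (x - xbar)^2) / sqrt(sum w (y - ybar)^2)
    with xbar = sum(w x)/sum(w). Bounded in [-1, 1]; affine-invariant
    (y = a x + b, a > 0 gives 1). Requires at least 3 strictly positive
    weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)) or len(x) < 3:
        raise ValueError("x, y, w must have equal length >= 3")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if (w > 0).sum() < 3:
        raise ValueError("insufficient support: fewer than 3 positive weights")
    sw = w.sum()
    xbar = (w @ x) / sw
    ybar = (w @ y) / sw
    xc = x - xbar
    yc = y - ybar
    den = math.sqrt(float(w @ (xc * xc))) * math.sqrt(float(w @ (yc * yc)))
    if den == 0:
        return math.nan
    return float(np.clip((w @ (xc * yc)) / den, -1.0, 1.0))


def run_until_converged(
    update,
    ec0: np.ndarray,
    tolerance: float = 0.1,
    max_iter: int = 100,
) -> ECResult:
    """Drive an EC update rule to convergence under the squared-change stop rule.

    ``update(prev, k)`` returns the EC vector of iteration k given the
    previous one. After each iteration, delta = nansum((cur - prev)^2); the
    loop stops with ``converged=True`` at the first k where delta <
    ``tolerance``, or with ``converged=False`` once ``max_iter`` iterations
    have run.
    """
    trace = [np.asarray(ec0, dtype=float)]
    delta_history: list[float] = []
    converged = False
    prev = trace[0]
    for k in range(1, max_iter + 1):
        cur = np.asarray(update(prev, k), dtype=float)
        delta = float(np.nansum((cur - prev) ** 2))
        trace.append(cur)
        delta_history.append(delta)
        prev = cur
        if delta < tolerance:
            converged = True
            break
    return ECResult(
        ec=prev, trace=trace, delta_history=delta_history,
        converged=converged, tolerance=tolerance,
    )


def ec_iterate(
    Ra: np.ndarray,
    Rb: np.ndarray,
    tolerance: float = 0.1,
    max_iter: int = 100,
) -> ECResult:
    """Run the iterative EC algorithm to convergence.

    trace[0] = EC_0. At iteration k, for every pair i (including pairs whose
    previous EC was <= 0 — the exclusion rule governs only which pairs
    contribute as weights):

        EC_k(i) = PCCw(Ra[i, g'], Rb[i, g'])  with
        g' = { l != i : EC_{k-1}(l) > 0 },  w_l = EC_{k-1}(l)

    stopping when sum_i (EC_k(i) - EC_{k-1}(i))^2 < tolerance, or flagging
    non-convergence at ``max_iter``. Pairs with undefined EC_0 (degenerate
    rows) are dropped from the computation with a logged warning and stay
    NaN throughout.
    """
    n = _check_square_pair(Ra, Rb)
    Ra = np.asarray(Ra, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    ec0 = ec_initial(Ra, Rb)
    active = ~np.isnan(ec0)
    if not active.all():
        dropped = list(np.flatnonzero(~active))
        logger.warning(
            "dropping %d ortholog pair(s) with undefined EC_0 (degenerate rows): %s",
            len(dropped), dropped,
        )
    def step(prev: np.ndarray, k: int) -> np.ndarray:
        positive = active & (prev > 0)
        cur = np.full(n, np.nan)
        for i in np.flatnonzero(active):
            gprime = positive.copy()
            gprime[i] = False
            if gprime.sum() < 3:
                raise ValueError(
                    f"weight support collapsed at iteration {k}: "
                    f"{int(gprime.sum())} positive-EC pairs available for pair {i}"
                )
            cur[i] = weighted_pcc(Ra[i, gprime], Rb[i, gprime], prev[gprime])
        return cur

    return run_until_converged(step, ec0, tolerance=tolerance, max_iter=max_iter)


@dataclass(frozen=True)
class MannWhitneySummary:
    u_statistic: float
    pvalue: float
    n1: int
    n2: int
    median1: float
    median2: float


def compare_ec_distributions(ec1, ec2) -> MannWhitneySummary:
    """Two-sided Mann-Whitney U (normal approximation with tie correction).

    The U statistic reported is for the first sample; complete separation of
    n1 vs n2 values gives U = n1*n2.
    """
    ec1 = np.asarray(ec1, dtype=float)
    ec2 = np.asarray(ec2, dtype=float)
    ec1 = ec1[~np.isnan(ec1)]
    ec2 = ec2[~np.isnan(ec2)]
    if len(ec1) == 0 or len(ec2) == 0:
        raise ValueError("both EC vectors must be non-empty")
    res = stats.mannwhitneyu(ec1, ec2, alternative="two-sided", method="asymptotic")
    return MannWhitneySummary(
        u_statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n1=len(ec1),
        n2=len(ec2),
        median1=float(np.median(ec1)),
        median2=float(np.median(ec2)),
    )


def ec_quantile_placement(genome_ec, subset_ec, q: float = 0.95) -> float:
    """Fraction of a gene subset at or above the genome-wide q-quantile.

    The quantile is the empirical nearest-rank quantile: the value at
    (1-based) position ceil(q * n) of the sorted genome-wide EC vector.
    Used to place e.g. a gene family's EC scores against the top 5% of the
    genome-wide distribution.
    """
    genome = np.asarray(genome_ec, dtype=float)
    genome = genome[~np.isnan(genome)]
    subset = np.asarray(subset_ec, dtype=float)
    subset = subset[~np.isnan(subset)]
    if len(genome) < 20:
        raise ValueError("genome-wide EC vector must have at least 20 values")
    if len(subset) == 0:
        raise ValueError("empty subset")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    cutoff = np.sort(genome)[math.ceil(q * len(genome)) - 1]
    # tiny slack so values mathematically equal to the cutoff are counted
    # regardless of floating-point summation order
    return float((subset >= cutoff - 1e-12).mean())


def ec_from_paired(
    paired: PairedExpression,
    tolerance: float = 0.1,
    max_iter: int = 100,
) -> ECResult:
    """Correlation matrices + iterative EC in one call on aligned matrices."""
    Ra = correlation_matrix(paired.matrix_a.to_numpy(dtype=float))
    Rb = correlation_matrix(paired.matrix_b.to_numpy(dtype=float))
    return ec_iterate(Ra, Rb, tolerance=tolerance, max_iter=max_iter)
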