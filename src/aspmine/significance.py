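"""Fisher exact tests on pattern contingency tables and Westfall-Young
permutation calibration of the family-wise error rate.

For a pattern q in a dataset with n+ allergens and n- nonallergens, the
2x2 table is (class membership) x (contains q).  With the margins n+, n-,
and the total support D[q] fixed, the probability of seeing the pattern in
exactly ``a`` allergens is hypergeometric::

    g(n+, n-, D[q], a) = C(n+, a) C(n-, D[q]-a) / C(n, D[q])

and the two-tailed p-value doubles the mass of all tables at most as
probable as the observed one:

    p = min(1, 2 * sum{ g(a) : g(a) <= g(a_obs) }).

Because billions of patterns are tested, per-test significance is
calibrated by the Westfall-Young permutation procedure: labels are
shuffled M times, the minimum p-value over all patterns is recorded for
each shuffle, and the adjusted level delta is the lower 100*alpha% point
of those M minima (the k-th smallest with k = ceil(alpha * M)).  A pattern
is declared significant when its raw p-value is strictly below delta,
which keeps the estimated FWER at (k-1)/M < alpha.

The naive calibration enumerates every pattern for every permutation.  The
fast calibration exploits a label-free lower bound on the p-value of a
pattern and all of its rightward extensions,

    p_low(D[q]) = min{ g(n+, n-, min(D[q], n+), min(D[q], n+)),
                       g(n+, n-, min(D[q], n-), 0) },

to cut subtrees that can no longer change the running minima: whenever
p_low exceeds the pruning threshold, no pattern in the subtree can update
any per-permutation minimum, so the whole branch is skipped.  By default
the threshold is the current *maximum* of the M running minima, which
makes the fast calibration bit-for-bit identical to the naive one
(including the full min-p distribution, hence adjusted p-values);
``prune_level="quantile"`` uses the current k-th smallest minimum instead,
pruning more aggressively while still reproducing delta and every minimum
below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .dataset import ProteinDataset
from .mining import Corpus, TraversalStats, _dfs

__all__ = [
    "ContingencyTable",
    "FETResult",
    "PermutationPlan",
    "WYCalibration",
    "hypergeom_g",
    "fet_pvalue",
    "pvalue_lower_bound",
    "generate_permutations",
    "wy_calibrate_naive",
    "wy_calibrate",
    "adjusted_pvalue",
    "bonferroni_level",
    "FETCalculator",
]

#: n at or below which tables are computed in exact rational arithmetic.
_EXACT_N = 64

#: log-space tolerance for hypergeometric probability ties in the float path.
_LOG_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ContingencyTable:
    n_pos: int
    n_neg: int
    d_all: int
    d_pos: int

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.d_all, self.d_pos) < 0:
            raise ValueError("contingency table entries must be nonnegative")
        if self.d_all > self.n_pos + self.n_neg:
            raise ValueError("support exceeds dataset size")
        lo = max(0, self.d_all - self.n_neg)
        hi = min(self.n_pos, self.d_all)
        if not lo <= self.d_pos <= hi:
            raise ValueError(f"d_pos={self.d_pos} outside admissible range [{lo}, {hi}]")


@dataclass
class FETResult:
    p_value: float
    tail_terms: list[tuple[int, float]]


def _g_exact(n_pos: int, n_neg: int, d_all: int, a: int) -> Fraction:
    return Fraction(
        math.comb(n_pos, a) * math.comb(n_neg, d_all - a),
        math.comb(n_pos + n_neg, d_all),
    )


def hypergeom_g(n_pos: int, n_neg: int, d_all: int, a: int) -> float:
    """Hypergeometric probability of the pattern appearing in ``a`` allergens."""
    if min(n_pos, n_neg, d_all) < 0:
        raise ValueError("negative inputs")
    if d_all > n_pos + n_neg:
        raise ValueError("d_all exceeds n_pos + n_neg")
    if a < max(0, d_all - n_neg) or a > min(n_pos, d_all):
        return 0.0
    if n_pos + n_neg <= _EXACT_N:
        return float(_g_exact(n_pos, n_neg, d_all, a))
    return math.exp(
        _log_comb(n_pos, a)
        + _log_comb(n_neg, d_all - a)
        - _log_comb(n_pos + n_neg, d_all)
    )


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


class FETCalculator:
    """Two-tailed FET p-values for a fixed (n_pos, n_neg), cached by support.

    ``table(d_all)`` returns a vector indexed by ``a`` (0..d_all) with the
    doubled-tail p-value for each admissible ``a`` (inadmissible entries
    hold NaN).  Exact rational arithmetic is used for n <= 64; above that,
    log-gamma probabilities with a tie tolerance of 1e-9 in log space.
    """

    def __init__(self, n_pos: int, n_neg: int):
        self.n_pos = n_pos
        self.n_neg = n_neg
        self.n = n_pos + n_neg
        self._tables: dict[int, np.ndarray] = {}
        self._lb: dict[int, float] = {}

    def table(self, d_all: int) -> np.ndarray:
        tbl = self._tables.get(d_all)
        if tbl is None:
            tbl = self._build(d_all)
            self._tables[d_all] = tbl
        return tbl

    def _admissible(self, d_all: int) -> tuple[int, int]:
        return max(0, d_all - self.n_neg), min(self.n_pos, d_all)

    def _build(self, d_all: int) -> np.ndarray:
        lo, hi = self._admissible(d_all)
        a_vals = list(range(lo, hi + 1))
        out = np.full(d_all + 1, np.nan)
        if self.n <= _EXACT_N:
            pmf = [_g_exact(self.n_pos, self.n_neg, d_all, a) for a in a_vals]
            for i, a in enumerate(a_vals):
                tail = sum(p for p in pmf if p <= pmf[i])
                out[a] = float(min(Fraction(1), 2 * tail))
            return out
        logs = np.array(
            [
                _log_comb(self.n_pos, a)
                + _log_comb(self.n_neg, d_all - a)
                - _log_comb(self.n, d_all)
                for a in a_vals
            ]
        )
        order = np.argsort(logs, kind="stable")
        logs_sorted = logs[order]
        csum = np.cumsum(np.exp(logs_sorted))
        idx = np.searchsorted(logs_sorted, logs + _LOG_TIE_TOL, side="right")
        out[lo : hi + 1] = np.minimum(1.0, 2.0 * csum[idx - 1])
        return out

    def pvalue(self, d_all: int, d_pos: int) -> float:
        return float(self.table(d_all)[d_pos])

    def lower_bound(self, d_all: int) -> float:
        """Label-free lower bound on the FET p-value of the pattern and all
        its extensions (min attainable single-tail probability)."""
        lb = self._lb.get(d_all)
        if lb is None:
            left = hypergeom_g(
                self.n_pos, self.n_neg, min(d_all, self.n_pos), min(d_all, self.n_pos)
            )
            right = hypergeom_g(self.n_pos, self.n_neg, min(d_all, self.n_neg), 0)
            lb = min(left, right)
            self._lb[d_all] = lb
        return lb


def fet_pvalue(table: ContingencyTable) -> FETResult:
    """Two-tailed Fisher exact test p-value with the doubled-tail rule."""
    calc = FETCalculator(table.n_pos, table.n_neg)
    lo, hi = calc._admissible(table.d_all)
    g_obs = hypergeom_g(table.n_pos, table.n_neg, table.d_all, table.d_pos)
    if table.n_pos + table.n_neg <= _EXACT_N:
        pmf = {
            a: _g_exact(table.n_pos, table.n_neg, table.d_all, a)
            for a in range(lo, hi + 1)
        }
        g_obs_x = pmf[table.d_pos]
        terms = [(a, float(p)) for a, p in pmf.items() if p <= g_obs_x]
        p = float(min(Fraction(1), 2 * sum(p for p in pmf.values() if p <= g_obs_x)))
        return FETResult(p, terms)
    log_obs = math.log(g_obs)
    terms = []
    total = 0.0
    for a in range(lo, hi + 1):
        g_a = hypergeom_g(table.n_pos, table.n_neg, table.d_all, a)
        if math.log(g_a) <= log_obs + _LOG_TIE_TOL:
            terms.append((a, g_a))
            total += g_a
    return FETResult(min(1.0, 2.0 * total), terms)


def pvalue_lower_bound(n_pos: int, n_neg: int, d_all: int) -> float:
    """Lower bound on fet_pvalue for any pattern of support <= d_all.

    Valid for the pattern itself and every rightward extension, under every
    label permutation (the bound does not look at labels).
    """
    if d_all < 0:
        raise ValueError("d_all must be nonnegative")
    return FETCalculator(n_pos, n_neg).lower_bound(d_all)


@dataclass
class PermutationPlan:
    m_perms: int
    seed: int
    label_matrix: np.ndarray  # (M, n) of int8 in {+1, -1}

    def pos_matrix(self) -> np.ndarray:
        return self.label_matrix == 1


def generate_permutations(dataset: ProteinDataset, m_perms: int, seed: int) -> PermutationPlan:
    """Draw M independent uniform permutations of the label vector.

    Labels are shuffled globally across the dataset (categories and
    sequences untouched), so every permuted vector has exactly n_pos
    positive entries.
    """
    if m_perms < 1:
        raise ValueError("m_perms must be >= 1")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    mat = np.empty((m_perms, len(labels)), dtype=np.int8)
    for m in range(m_perms):
        mat[m] = rng.permutation(labels)
    return PermutationPlan(m_perms, seed, mat)


@dataclass
class WYCalibration:
    min_p: np.ndarray  # per-permutation minimum p-values, length M
    alpha: float
    k: int
    delta: float
    fwer_estimate: float
    m_perms: int
    stats: TraversalStats = field(default_factory=TraversalStats)

    def to_report(self) -> dict:
        hist, edges = np.histogram(self.min_p, bins=20)
        return {
            "alpha": self.alpha,
            "m_perms": self.m_perms,
            "k": self.k,
            "delta": self.delta,
            "fwer_estimate": self.fwer_estimate,
            "min_p_histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
            "nodes_visited": self.stats.nodes_visited,
            "subtrees_pruned": self.stats.subtrees_pruned,
        }


def _finalize(min_p: np.ndarray, alpha: float, stats: TraversalStats) -> WYCalibration:
    m = len(min_p)
    k = math.ceil(alpha * m)
    delta = float(np.sort(min_p)[k - 1])
    fwer = float(np.mean(min_p < delta))
    return WYCalibration(min_p, alpha, k, delta, fwer, m, stats)


def _calibrate(
    dataset: ProteinDataset | Corpus,
    plan: PermutationPlan,
    alpha: float,
    min_support: int,
    prune_level: Optional[str],
) -> WYCalibration:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    corpus = dataset if isinstance(dataset, Corpus) else Corpus(dataset)
    pos_mat = plan.pos_matrix()
    m = plan.m_perms
    fet = FETCalculator(corpus.n_pos, corpus.n_neg)
    min_p = np.ones(m)
    k = math.ceil(alpha * m)
    stats = TraversalStats()
    state = {"threshold": 1.0}

    def handle(depth: int, occ: np.ndarray, prots: np.ndarray) -> bool:
        d_all = len(prots)
        if prune_level is not None and fet.lower_bound(d_all) > state["threshold"]:
            return True
        d_pos = pos_mat[:, prots].sum(axis=1)
        p = fet.table(d_all)[d_pos]
        np.minimum(min_p, p, out=min_p)
        if prune_level == "quantile":
            state["threshold"] = float(np.partition(min_p, k - 1)[k - 1])
        elif prune_level == "distribution":
            state["threshold"] = float(min_p.max())
        return False

    _dfs(corpus, min_support, None, handle, stats)
    return _finalize(min_p, alpha, stats)


def wy_calibrate_naive(
    dataset: ProteinDataset | Corpus,
    plan: PermutationPlan,
    alpha: float = 0.05,
    min_support: int = 1,
) -> WYCalibration:
    """Full-enumeration Westfall-Young calibration (oracle for the fast path)."""
    return _calibrate(dataset, plan, alpha, min_support, prune_level=None)


def wy_calibrate(
    dataset: ProteinDataset | Corpus,
    plan: PermutationPlan,
    alpha: float = 0.05,
    min_support: int = 1,
    prune_level: str = "distribution",
) -> WYCalibration:
    """Westfall-Young calibration with branch-and-bound pruning.

    ``prune_level="distribution"`` (default) reproduces the naive
    calibration bit-for-bit; ``"quantile"`` prunes against the running
    k-th smallest minimum and guarantees only delta and the minima below it.
    """
    if prune_level not in ("distribution", "quantile"):
        raise ValueError("prune_level must be 'distribution' or 'quantile'")
    return _calibrate(dataset, plan, alpha, min_support, prune_level=prune_level)


def adjusted_pvalue(p_raw: float, calibration: WYCalibration) -> float:
    """Empirical WY adjusted p-value: fraction of permutation minima <= p_raw."""
    return float(np.mean(calibration.min_p <= p_raw))


def bonferroni_level(alpha: float, n_tests: int) -> float:
    """Reference Bonferroni per-test level alpha / T."""
    return alpha / n_tests
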