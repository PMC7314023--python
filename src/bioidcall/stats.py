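"""The S0-moderated two-sample statistic and its significance machinery.

The statistic is the SAM-style moderation of the pooled two-sample t:

    d = (mean(x) - mean(y)) / (s_p * sqrt(1/n1 + 1/n2) + s0)

where ``s_p`` is the pooled standard deviation and ``s0 >= 0`` is a fudge
factor that damps the significance of small-variance, small-difference
proteins.  At ``s0 = 0`` the statistic is exactly the classical pooled
two-sample t.

Two significance routes are offered:

* an analytic two-sided p treating ``d`` as t-distributed with ``n1+n2-2``
  degrees of freedom — exact at ``s0 = 0`` and conservative for ``s0 > 0``
  (the +s0 denominator only shrinks ``|d|``);
* a permutation FDR (the recommended default): the observed ``|d|`` of each
  protein is compared against the pooled null distribution of ``|d|`` over
  group-label permutations of the whole table, giving a plug-in q-value

      q(t) = E_perm[ #{null |d| >= t} ] / #{observed |d| >= t}

  made monotone non-increasing in ``|d|`` and clipped to [0, 1].  No
  pi0 estimate is applied (pi0 = 1, conservative).

Missing values are never imputed: a protein without at least
``min_valid_per_group`` detected replicates in each group is excluded from
testing and must be handled by the exclusivity classifier instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import IntensityTable

__all__ = [
    "TestPolicy",
    "ModeratedTestResult",
    "InsufficientReplicatesError",
    "moderated_two_sample",
    "permutation_qvalues",
    "significance_flag",
]


class InsufficientReplicatesError(ValueError):
    """Too few detected replicates for the moderated test.

    Callers should route such proteins to the exclusivity classifier
    (:func:`bioidcall.interactors.classify_exclusive`) instead of imputing.
    """


@dataclass(frozen=True)
class TestPolicy:
    """Parameters of the significance machinery.

    s0
        fudge factor added to the denominator of the statistic (default 0.1).
    min_valid_per_group
        minimum detected replicates per group for a protein to be testable.
    alpha
        threshold on the q-value (permutation mode) or analytic p for the
        significance flag.
    use_permutation / n_perm / seed
        permutation FDR is the default route; all distinct label assignments
        are enumerated when there are at most ``n_perm`` of them, otherwise
        ``n_perm`` assignments are sampled with the stated seed.
    """

    __test__ = False  # not a test class, despite the pytest-style name

    s0: float = 0.1
    min_valid_per_group: int = 2
    alpha: float = 0.05
    use_permutation: bool = True
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.min_valid_per_group < 2:
            raise ValueError("min_valid_per_group must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.use_permutation and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 when permutation FDR is used")

    def with_seed(self, seed: int) -> "TestPolicy":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class ModeratedTestResult:
    d: float          # moderated statistic
    diff: float       # mean(x) - mean(y) on the log2 scale
    n1: int
    n2: int
    s0: float
    p_analytic: float
    q_perm: float | None = None


def moderated_two_sample(x, y, s0: float = 0.1) -> ModeratedTestResult:
    """S0-moderated two-sample statistic for two complete replicate vectors.

    ``x`` and ``y`` must contain only detected (non-missing) log2 values, at
    least two each.  ``d`` carries the sign of ``mean(x) - mean(y)``; the
    analytic p is two-sided from a t distribution with ``n1+n2-2`` df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("x and y must not contain missing values")
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"need >=2 values per group (got {n1} and {n2}); "
            "use the exclusivity path for presence/absence proteins"
        )
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    diff = x.mean() - y.mean()
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2) * np.sqrt(1.0 / n1 + 1.0 / n2)
    denom = se + s0
    d = 0.0 if diff == 0 else (diff / denom if denom > 0 else np.inf * np.sign(diff))
    p = float(2.0 * sps.t.sf(abs(d), df)) if np.isfinite(d) else 0.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return ModeratedTestResult(
        d=float(d), diff=float(diff), n1=n1, n2=n2, s0=float(s0), p_analytic=p
    )


# ---------------------------------------------------------------------------
# vectorised core shared by the permutation machinery
# ---------------------------------------------------------------------------

def row_nanmean(M: np.ndarray) -> np.ndarray:
    """Row means over detected values; NaN for all-missing rows, no warnings."""
    cnt = np.sum(~np.isnan(M), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.nansum(M, axis=1) / cnt
    return np.where(cnt > 0, m, np.nan)


def _row_nanvar(M: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Row sample variances (ddof=1) over detected values; NaN when <2."""
    cnt = np.sum(~np.isnan(M), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.nansum((M - mean[:, None]) ** 2, axis=1)
        v = ss / (cnt - 1)
    return np.where(cnt > 1, v, np.nan)


def _d_for_assignment(
    values: np.ndarray, g1_idx: np.ndarray, g2_idx: np.ndarray, s0: float, min_valid: int
) -> np.ndarray:
    """Per-row moderated d for one label assignment; NaN where untestable."""
    a, b = values[:, g1_idx], values[:, g2_idx]
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    ok = (n1 >= min_valid) & (n2 >= min_valid)
    m1 = row_nanmean(a)
    m2 = row_nanmean(b)
    v1 = _row_nanvar(a, m1)
    v2 = _row_nanvar(b, m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2) * np.sqrt(1.0 / n1 + 1.0 / n2)
        d = (m1 - m2) / (se + s0)
        if s0 == 0:
            d = np.where((m1 - m2) == 0, 0.0, d)  # 0/0 -> 0, matching diff=0
    d = np.where(ok, d, np.nan)
    return d


def _assignments(n_total: int, n1: int, n_perm: int, seed: int) -> list[np.ndarray]:
    """Null label assignments: distinct n1-subsets of range(n_total).

    The identity assignment (and, for balanced groups, its complement, which
    yields the same ``|d|``) is excluded so the null never contains the
    observed labeling itself; all remaining assignments are enumerated when
    there are at most ``n_perm`` of them, otherwise ``n_perm`` are sampled
    with the stated seed.
    """
    from math import comb

    identity = tuple(range(n1))
    complement = tuple(range(n1, n_total)) if n_total == 2 * n1 else None
    total = comb(n_total, n1) - 1 - (complement is not None)
    if total < 2:
        raise ValueError("fewer than 2 distinct label permutations possible")
    if total <= n_perm:
        return [
            np.array(c)
            for c in itertools.combinations(range(n_total), n1)
            if c != identity and c != complement
        ]
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    while len(out) < n_perm:
        c = tuple(np.sort(rng.permutation(n_total)[:n1]))
        if c != identity and c != complement:
            out.append(np.array(c))
    return out


def permutation_qvalues(
    table: IntensityTable,
    group1: list[str],
    group2: list[str],
    policy: TestPolicy,
) -> pd.Series:
    """Permutation-FDR q-values for group1-vs-group2 across the whole table.

    Returns a Series indexed like the table; proteins with fewer than
    ``min_valid_per_group`` detected values in either group are excluded from
    testing and carry NaN.  Identical rows receive identical q-values, and q
    is monotone non-increasing in ``|d|``.  A protein whose ``|d|`` exceeds
    every permuted ``|d|`` in the table gets q = 0 (plug-in convention: the
    estimated null exceedance count is zero).
    """
    samples = list(group1) + list(group2)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("both groups need at least 2 samples")
    values = table.matrix(samples)
    n1 = len(group1)
    obs_idx = np.arange(len(samples))
    d_obs = _d_for_assignment(
        values, obs_idx[:n1], obs_idx[n1:], policy.s0, policy.min_valid_per_group
    )

    null_abs: list[np.ndarray] = []
    assignments = _assignments(len(samples), n1, policy.n_perm, policy.seed)
    all_idx = np.arange(len(samples))
    for g1 in assignments:
        g2 = np.setdiff1d(all_idx, g1, assume_unique=True)
        d_perm = _d_for_assignment(
            values, g1, g2, policy.s0, policy.min_valid_per_group
        )
        null_abs.append(np.abs(d_perm[~np.isnan(d_perm)]))
    n_assign = len(assignments)
    pooled_null = np.sort(np.concatenate(null_abs)) if null_abs else np.array([])

    abs_obs = np.abs(d_obs)
    testable = ~np.isnan(abs_obs)
    q = np.full(len(abs_obs), np.nan)
    if testable.any():
        t_vals = abs_obs[testable]
        # E_perm[#null >= t] and #obs >= t via sorted searches
        null_ge = len(pooled_null) - np.searchsorted(pooled_null, t_vals, side="left")
        sorted_obs = np.sort(t_vals)
        obs_ge = len(sorted_obs) - np.searchsorted(sorted_obs, t_vals, side="left")
        q_raw = (null_ge / n_assign) / np.maximum(obs_ge, 1)
        # enforce monotone non-increasing in |d|: running min in ascending order
        order = np.argsort(t_vals, kind="stable")
        q_sorted = np.minimum.accumulate(q_raw[order])
        q_mon = np.empty_like(q_raw)
        q_mon[order] = q_sorted
        q[testable] = np.clip(q_mon, 0.0, 1.0)
    return pd.Series(q, index=table.data.index, name="q_perm")


def significance_flag(result: ModeratedTestResult, policy: TestPolicy) -> bool:
    """The "+" significance mark: q <= alpha in permutation mode, else p <= alpha.

    Direction is not considered here; callers check ``diff > 0`` themselves.
    """
    if policy.use_permutation and result.q_perm is not None:
        return bool(result.q_perm <= policy.alpha)
    return bool(result.p_analytic <= policy.alpha)
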