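"""Group-difference inference for network attributes and connectivity.

Three inferential tools, mirroring how staged-cohort connectome studies
compare groups:

* a nonparametric permutation test on scalar features (metric AUCs):
  group labels are randomly reallocated, preserving group sizes, to build
  the null distribution of the mean difference;
* mass-univariate Welch two-sample t-tests on edge weights or network
  pair functional connectivity (optionally on Fisher z-transformed
  correlations), corrected across the family by Benjamini-Hochberg FDR;
* Pearson correlation of per-subject values with MMSE scores.

Permutation p-values use the +1 correction p = (1 + #extreme) / (B + 1),
which keeps the test valid (p is never exactly 0).  Three tail modes
exist:

* ``two_tailed`` (recommended default for inference) compares absolute
  differences;
* ``one_tailed_greater`` tests the fixed, a-priori direction
  mean(a) > mean(b);
* ``one_tailed_directional`` picks the tail from the sign of the
  observed difference.  Caution: because the direction is chosen after
  seeing the data, this test's p-values are uniform on (0, 0.5) under
  the null, so its type-I error at level alpha is 2*alpha.  It is kept
  for exploratory, direction-agnostic screening only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "ComparisonResult",
    "permutation_test",
    "bh_fdr",
    "fisher_z",
    "edge_t_test",
    "welch_t_test",
    "mmse_correlation",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 10_000
    tail: str = "one_tailed_directional"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in ("one_tailed_directional", "one_tailed_greater", "two_tailed"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int


@dataclass(frozen=True)
class ComparisonResult:
    """One feature's group comparison after FDR correction."""

    contrast: tuple[str, str]
    feature: str
    observed_diff: float
    p_value: float
    q_value: float
    reject: bool
    degenerate: bool = False


def permutation_test(a, b, cfg: PermutationConfig | None = None) -> PermutationResult:
    """Permutation test of mean(a) - mean(b).

    The null distribution is built from ``cfg.n_permutations`` random
    reallocations of the pooled values into groups of the original sizes.
    One-tailed directional mode counts null differences at least as
    extreme as the observed one *on the observed side*; two-tailed mode
    compares absolute differences.  Reproducible under ``cfg.seed``.
    """
    if cfg is None:
        cfg = PermutationConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 values per group, got {len(a)} and {len(b)}")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)
    rng = np.random.default_rng(cfg.seed)
    # vectorized relabeling: each row of `order` is one permutation
    order = np.argsort(rng.random((cfg.n_permutations, n)), axis=1)
    perm = pooled[order]
    null = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
    if cfg.tail == "two_tailed":
        extreme = np.abs(null) >= abs(observed) - 1e-12
    elif cfg.tail == "one_tailed_greater":
        extreme = null >= observed - 1e-12
    elif observed >= 0:
        extreme = null >= observed - 1e-12
    else:
        extreme = null <= observed + 1e-12
    p = (1 + int(extreme.sum())) / (cfg.n_permutations + 1)
    return PermutationResult(observed_diff=observed, p_value=float(p),
                             n_permutations=cfg.n_permutations)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (q_values, reject) where q_(i) = min_{j >= i} m * p_(j) / j
    capped at 1, and reject <=> q <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def fisher_z(r, clip: float = 1 - 1e-7) -> np.ndarray:
    """Fisher z-transform arctanh(r), with |r| clipped below 1."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -clip, clip))


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch two-sample t-test along axis 0.

    Returns (t, p_two_sided, degenerate) per column; columns with zero
    variance in both groups are flagged degenerate and given p = 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    safe = np.where(degenerate, 1.0, se2)
    t = (ma - mb) / np.sqrt(safe)
    df = safe**2 / np.where(
        degenerate, 1.0,
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(np.abs(t), df)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate


def edge_t_test(group_a: list[np.ndarray], group_b: list[np.ndarray],
                contrast: tuple[str, str] = ("A", "B"), *,
                fisher: bool = True, alpha: float = 0.05) -> list[ComparisonResult]:
    """Edge-wise group comparison of connectivity matrices.

    For every unordered ROI pair the edge weights are (optionally) Fisher
    z-transformed, compared with a Welch t-test, and the p-values are
    BH-FDR corrected across all edges as one family.  The reported
    ``observed_diff`` is on the original correlation scale.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 subjects per group")
    n = group_a[0].shape[0]
    iu = np.triu_indices(n, k=1)
    stack_a = np.stack([m[iu] for m in group_a])
    stack_b = np.stack([m[iu] for m in group_b])
    diff = stack_a.mean(axis=0) - stack_b.mean(axis=0)
    ta, tb = (fisher_z(stack_a), fisher_z(stack_b)) if fisher else (stack_a, stack_b)
    _, p, degenerate = welch_t_test(ta, tb)
    q, reject = bh_fdr(p, alpha=alpha)
    return [
        ComparisonResult(
            contrast=contrast, feature=f"{i}-{j}", observed_diff=float(diff[e]),
            p_value=float(p[e]), q_value=float(q[e]), reject=bool(reject[e]),
            degenerate=bool(degenerate[e]),
        )
        for e, (i, j) in enumerate(zip(*iu))
    ]


def mmse_correlation(values, mmse) -> tuple[float, float]:
    """Pearson correlation of per-subject values with MMSE scores.

    Returns (r, p) with the two-sided p-value from the t-distribution
    with n - 2 degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    mmse = np.asarray(mmse, dtype=float)
    if values.shape != mmse.shape or values.ndim != 1:
        raise ValueError("values and mmse must be equal-length 1-D arrays")
    if len(values) < 4:
        raise ValueError("need at least 4 paired observations")
    if (values == values[0]).all() or (mmse == mmse[0]).all():
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(values, mmse)
    return float(r), float(p)
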