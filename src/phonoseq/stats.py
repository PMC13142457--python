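"""Electrode-level tests, FDR correction, and resampling primitives."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import EvaluationError, PhonoseqError


@dataclass
class TuningTestResult:
    pvalues: np.ndarray          # per feature; NaN where degenerate
    test: str
    group_sizes: np.ndarray
    delta: np.ndarray | None     # difference of group means (2-group Welch)
    se_delta: np.ndarray | None  # sqrt(s1²/n1 + s2²/n2)
    rejected: np.ndarray | None = None
    adjusted_p: np.ndarray | None = None


def tuning_tests(groups, test: str = "welch") -> TuningTestResult:
    """Per-feature p-values across trial groups of window-summed activity.

    ``groups`` is a sequence of (n_i, F) matrices, one per condition group.
    ``welch`` (2 groups) also returns the mean difference Δ = μ₂ - μ₁ and
    its propagated standard error; ``kruskal`` handles >= 2 groups.
    Features degenerate in any group (zero spread under kruskal, single
    trial under welch) get NaN p-values and are flagged by exclusion.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if len(groups) < 2 or any(g.shape[0] < 2 for g in groups):
        raise PhonoseqError("need >= 2 groups with >= 2 trials each")
    f = groups[0].shape[1]
    sizes = np.array([g.shape[0] for g in groups])

    if test == "welch":
        if len(groups) != 2:
            raise PhonoseqError("welch mode is two-group")
        a, b = groups
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = sps.ttest_ind(b, a, axis=0, equal_var=False)
        delta = b.mean(axis=0) - a.mean(axis=0)
        se = np.sqrt(a.var(axis=0, ddof=1) / len(a)
                     + b.var(axis=0, ddof=1) / len(b))
        p = np.where(np.isfinite(p), p, np.nan)
        return TuningTestResult(
            pvalues=p, test="welch", group_sizes=sizes,
            delta=delta, se_delta=se,
        )
    if test == "kruskal":
        p = np.empty(f)
        with np.errstate(invalid="ignore", divide="ignore"):
            for j in range(f):
                cols = [g[:, j] for g in groups]
                try:
                    _, p[j] = sps.kruskal(*cols)
                except ValueError:        # all values identical
                    p[j] = np.nan
        return TuningTestResult(
            pvalues=p, test="kruskal", group_sizes=sizes,
            delta=None, se_delta=None,
        )
    raise ValueError(f"unknown test {test!r}")


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR over one explicit test family.

    NaN entries (degenerate features) are excluded from the family and
    reported as not rejected.  Returns (rejected mask, adjusted p).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise PhonoseqError("p-values must lie in [0, 1]")
    ok = np.isfinite(p)
    rejected = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        rejected[ok] = rej
        adjusted[ok] = adj
    return rejected, adjusted


def bootstrap_ci(statistic, data, n_boot: int = 10000, level: float = 0.95,
                 seed: int = 0):
    """Percentile bootstrap CI for ``statistic(resampled rows of data)``.

    ``data`` may be one array or a tuple of arrays resampled jointly along
    axis 0.  Resamples on which the statistic is undefined (raises or
    returns non-finite) are dropped and counted.
    """
    parts = data if isinstance(data, (tuple, list)) else (data,)
    parts = [np.asarray(d) for d in parts]
    n = parts[0].shape[0]
    if n == 0:
        raise PhonoseqError("empty data")
    rng = np.random.default_rng(seed)
    vals, dropped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(*(d[idx] for d in parts))
        except Exception:
            dropped += 1
            continue
        if np.isscalar(v) and not np.isfinite(v):
            dropped += 1
            continue
        vals.append(v)
    if not vals:
        raise EvaluationError("statistic undefined on every resample")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(np.asarray(vals, dtype=float),
                         [alpha, 1 - alpha], axis=0)
    return float(lo), float(hi), dropped


@dataclass
class PermutationResult:
    p: float
    observed: float
    min_p: float                 # resolution floor 1/n_perm
    null: np.ndarray


def permutation_test(statistic, data, labels, n_perm: int = 10000,
                     alternative: str = "greater", seed: int = 0
                     ) -> PermutationResult:
    """Label-shuffle permutation p-value, raw-fraction definition.

    ``p = (number of permuted statistics >= observed) / n_perm`` for the
    ``greater`` alternative (``<=`` for ``less``); the resolution floor
    ``1/n_perm`` is reported alongside so p=0 reads as p < 1/n_perm.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(statistic(data, labels))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic(data, rng.permutation(labels))
    if np.ptp(null) == 0 and null[0] == observed:
        raise EvaluationError(
            "statistic constant under all permutations (degenerate)"
        )
    if alternative == "greater":
        p = float(np.mean(null >= observed))
    elif alternative == "less":
        p = float(np.mean(null <= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationResult(
        p=p, observed=observed, min_p=1.0 / n_perm, null=null
    )
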