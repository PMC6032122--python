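"""Subject-matched baselines, bootstrap CIs, and permutation tests.

Individual observers differ in both microsaccade rate and sensitivity,
so a perisaccadic bin and its baseline can have different subject mixes.
Baseline thresholds are therefore computed on subsamples of the baseline
pool whose per-subject proportions match the bin's (largest-remainder
rounding), averaged over a fixed number of replicates (50 by default).

Bootstrap CIs resample trials with replacement *before* binning and
re-run the statistic; permutation tests pool two trial groups, permute
the labels preserving group sizes, and compare |delta log10 threshold|
with an add-one correction, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatchedBaseline", "largest_remainder", "subject_match",
    "bootstrap_ci", "permutation_test",
]


@dataclass
class MatchedBaseline:
    """Replicate thresholds from subject-proportion-matched subsamples."""

    replicate_thresholds: np.ndarray
    mean_threshold: float
    subsample_size: int
    n_reps: int


def largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``proportions``."""
    proportions = np.asarray(proportions, dtype=float)
    quota = proportions / proportions.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return counts


def subject_match(baseline: pd.DataFrame, bin_trials: pd.DataFrame,
                  fit_fn, n_reps: int = 50, rng=None,
                  subsample_size: int | None = None) -> MatchedBaseline:
    """Baseline threshold with per-subject proportions matched to a bin.

    Each of ``n_reps`` replicates draws, without replacement, from each
    subject's baseline pool in the bin's subject proportions
    (largest-remainder rounding); ``fit_fn`` maps a trial DataFrame to a
    threshold and the result is the mean over replicates.

    The default subsample size is the largest size every subject's pool
    can support at the target proportions, capped at the baseline size.
    """
    rng = np.random.default_rng(rng)
    comp = bin_trials["subject"].value_counts(normalize=True)
    subjects = list(comp.index)
    props = comp.to_numpy()
    pools = {s: baseline[baseline["subject"] == s] for s in subjects}
    for s in subjects:
        if len(pools[s]) == 0:
            raise ValueError(f"subject {s!r} has no baseline trials")
    if subsample_size is None:
        cap = min(int(len(pools[s]) / p) for s, p in zip(subjects, props))
        subsample_size = max(min(cap, len(baseline)), len(subjects))
    counts = largest_remainder(props, subsample_size)
    # guard: rounding can exceed a small pool by one
    counts = np.minimum(counts, [len(pools[s]) for s in subjects])
    thresholds = np.empty(n_reps)
    for r in range(n_reps):
        parts = []
        for s, k in zip(subjects, counts):
            pool = pools[s]
            take = rng.choice(len(pool), size=int(k), replace=False)
            parts.append(pool.iloc[take])
        thresholds[r] = fit_fn(pd.concat(parts, ignore_index=True))
    return MatchedBaseline(replicate_thresholds=thresholds,
                           mean_threshold=float(thresholds.mean()),
                           subsample_size=int(counts.sum()), n_reps=n_reps)


def bootstrap_ci(trials: pd.DataFrame, statistic, n_boot: int = 1000,
                 level: float = 0.95, rng=None, max_redraws: int = 10):
    """Percentile bootstrap CI of ``statistic(trials)``.

    Trials are resampled with replacement from the full set before any
    binning inside ``statistic``.  A replicate on which the statistic
    fails (raises) is redrawn, up to ``max_redraws`` extra attempts per
    replicate; the redraw count is reported.

    Returns ``(estimate, lo, hi, boots, n_redrawn)`` where ``estimate``
    is the statistic on the original data (may be a scalar or array).
    """
    rng = np.random.default_rng(rng)
    est = np.asarray(statistic(trials), dtype=float)
    boots = np.empty((n_boot,) + est.shape)
    n = len(trials)
    redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(n, size=n)
            try:
                boots[b] = np.asarray(statistic(trials.iloc[idx]), dtype=float)
                break
            except Exception:
                redrawn += 1
        else:
            boots[b] = np.nan
    alpha = (1.0 - level) / 2.0
    lo = np.nanquantile(boots, alpha, axis=0)
    hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return est, lo, hi, boots, redrawn


def permutation_test(group_a: pd.DataFrame, group_b: pd.DataFrame,
                     fit_fn, n_perm: int = 1000, rng=None):
    """Two-sided permutation test on |delta log10 threshold|.

    Pools the two trial groups, permutes labels preserving sizes, refits
    both thresholds per permutation; p = (1 + #{perm >= observed}) /
    (n_perm + 1).  Returns ``(p, observed, null_stats)``.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(rng)
    observed = abs(fit_fn(group_a) - fit_fn(group_b))
    pooled = pd.concat([group_a, group_b], ignore_index=True)
    na = len(group_a)
    n = len(pooled)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = abs(fit_fn(pooled.iloc[perm[:na]])
                      - fit_fn(pooled.iloc[perm[na:]]))
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return float(p), float(observed), null
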