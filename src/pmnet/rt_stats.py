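"""Response-time distribution statistics.

Three tools recur throughout the analyses: the coefficient of variation
(CV = SD/mean, a scale-free dispersion measure — proportional slowing of
a distribution changes the mean but not the CV), a sample-size-matched
"unbiased" CV computed by repeatedly subsampling a large reference
condition down to the size of a rare condition, and vincentized group
RT distributions (per-subject equal-probability quantile bins averaged
across subjects).

Conventions: the sample (n-1) SD is used throughout; subsampling is
without replacement; quantile bins are formed by fractional allocation
of the sorted observations, i.e. observation k of n contributes to bin b
in proportion to the overlap of [k/n, (k+1)/n) with [b/B, (b+1)/B).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["cv", "unbiased_cv", "vincentize", "synthetic_rt_sample",
           "read_rt_file", "cv_table"]


def _as_sample(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1:
        raise ValueError("RT sample must be one-dimensional")
    if np.any(arr <= 0):
        raise ValueError("RTs must be positive")
    return arr


def cv(sample) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) / mean."""
    arr = _as_sample(sample)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 observations")
    return float(arr.std(ddof=1) / arr.mean())


def unbiased_cv(reference, n_match: int, reps: int = 100_000,
                rng: np.random.Generator | None = None) -> float:
    """Mean CV over random subsamples matched in size to a rarer condition.

    Draws ``reps`` subsamples of size ``n_match`` without replacement
    from ``reference`` and returns the mean of their CVs.  With
    ``n_match`` equal to the reference size every subsample is the full
    sample and the result equals ``cv(reference)`` exactly.
    """
    arr = _as_sample(reference)
    if not 2 <= n_match <= arr.size:
        raise ValueError("n_match must be in [2, len(reference)]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_match == arr.size:
        return cv(arr)
    if rng is None:
        rng = np.random.default_rng()
    # vectorized subsampling: argsort of uniform keys gives independent
    # permutations; the first n_match columns are a sample w/o replacement
    total = 0.0
    chunk = max(1, int(5e7) // arr.size)
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        keys = rng.random((k, arr.size))
        idx = np.argpartition(keys, n_match - 1, axis=1)[:, :n_match]
        sub = arr[idx]
        total += float(np.sum(sub.std(ddof=1, axis=1) / sub.mean(axis=1)))
        done += k
    return total / reps


def vincentize(per_subject_samples, n_bins: int = 10) -> np.ndarray:
    """Group RT distribution by averaging per-subject quantile-bin means.

    Each subject's RTs are partitioned into ``n_bins`` equal-probability
    bins (fractional allocation over the sorted sample), the mean RT of
    each bin is taken, and bin means are averaged across subjects.
    Subjects with fewer than ``n_bins`` observations are excluded with a
    warning.  The returned bin means are non-decreasing.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rows = []
    for i, sample in enumerate(per_subject_samples):
        arr = _as_sample(sample)
        if arr.size < n_bins:
            warnings.warn(
                f"subject {i}: n={arr.size} < n_bins={n_bins}, excluded")
            continue
        rows.append(_bin_means(np.sort(arr), n_bins))
    if not rows:
        raise ValueError("no subject had enough observations")
    return np.mean(rows, axis=0)


def _bin_means(sorted_rts: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-probability bin means with interpolation at bin edges.

    Sorted observation k of n occupies the probability interval
    [k/n, (k+1)/n); bin b receives each observation weighted by its
    overlap with [b/B, (b+1)/B).
    """
    n = sorted_rts.size
    lo = np.arange(n) / n
    hi = lo + 1.0 / n
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = np.empty(n_bins)
    for b in range(n_bins):
        overlap = np.clip(np.minimum(hi, edges[b + 1])
                          - np.maximum(lo, edges[b]), 0.0, None)
        out[b] = np.sum(overlap * sorted_rts) * n_bins
    return out


def synthetic_rt_sample(n: int, rng: np.random.Generator,
                        shift: float = 300.0, mu: float = 5.0,
                        sigma: float = 0.5) -> np.ndarray:
    """Synthetic right-skewed RT sample (shifted lognormal).

    Returns ``shift + LogNormal(mu, sigma)`` draws — a standard shape
    for empirical RT distributions — for exercising the statistics in
    this module without running any network simulation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return shift + rng.lognormal(mu, sigma, size=n)


def read_rt_file(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a trial-level RT file with columns
    ``subject, condition, trial_class, rt``."""
    df = pd.read_csv(path, sep=delimiter)
    required = {"subject", "condition", "trial_class", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def cv_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, condition, trial_class) mean RT, SD and CV."""
    def _stats(group):
        rts = group["rt"].to_numpy(dtype=float)
        return pd.Series({
            "n": rts.size,
            "mean_rt": rts.mean(),
            "sd_rt": rts.std(ddof=1) if rts.size >= 2 else np.nan,
            "cv": cv(rts) if rts.size >= 2 else np.nan,
        })
    grouped = df.groupby(["subject", "condition", "trial_class"])
    return grouped.apply(_stats, include_groups=False).reset_index()
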