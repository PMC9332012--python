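"""Agreement statistics between true tiller counts and estimated counts.

Field evaluations of hill-level counting report a standard statistic set:
a binned error histogram (open-ended at |error| >= 7), its count-weighted
mean, the fraction of hills within ±k tillers, the Pearson correlation and a
paired t-test between truth and estimate, and the behaviour of the error
when several hills are averaged together (the error SD of a group average
shrinks roughly as 1/sqrt(group size) when per-hill errors are independent).

The module also ships, as plain-text fixtures, the nine published error
histograms from the field campaign this pipeline was designed against
(three comparison pairs x three observation dates), so the summary
statistics can be recomputed from the binned counts.

Sign convention: error = estimate − truth throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

__all__ = [
    "BIN_LABELS",
    "ErrorHistogram",
    "error_histogram",
    "histogram_mean",
    "fraction_within",
    "paired_stats",
    "group_average_error",
    "load_field_histogram",
    "field_histogram_keys",
]

#: Histogram bins: open-ended at both extremes, unit bins between.
BIN_VALUES = list(range(-7, 8))
BIN_LABELS = ["-7 or less"] + [str(v) for v in range(-6, 7)] + ["7 or more"]

_COMPARISONS = ("true_manual", "manual_auto", "true_auto")
_DATES = ("jul03", "jul23", "aug07")


@dataclass(frozen=True)
class ErrorHistogram:
    """Integer counts over the 15 error bins {<=-7, -6, ..., +6, >=+7}."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(BIN_VALUES):
            raise ValueError(f"expected {len(BIN_VALUES)} bins, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("bin counts must be >= 0")

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def error_histogram(obs) -> ErrorHistogram:
    """Bin the per-hill errors ``estimate − truth`` of paired observations.

    ``obs`` is a sequence of (truth, estimate) integer pairs.  Errors beyond
    ±6 fall into the open extreme bins.
    """
    obs = list(obs)
    if not obs:
        raise ValueError("no paired observations")
    counts = [0] * len(BIN_VALUES)
    for truth, est in obs:
        if truth < 0 or est < 0:
            raise ValueError("counts must be >= 0")
        err = int(est) - int(truth)
        counts[min(max(err, -7), 7) + 7] += 1
    return ErrorHistogram(tuple(counts))


def histogram_mean(h: ErrorHistogram, open_bin_magnitude: int = 7) -> float:
    """Count-weighted mean error, rounded to 2 decimals.

    The open extreme bins are valued at ∓/± ``open_bin_magnitude``; with 7
    (the default) the mean of a histogram without open-bin mass equals the
    exact sample mean of the binned errors.
    """
    if h.n == 0:
        raise ValueError("empty histogram")
    values = np.array(BIN_VALUES, dtype=float)
    values[0] = -open_bin_magnitude
    values[-1] = open_bin_magnitude
    return round(float(np.dot(values, h.counts) / h.n), 2)


def fraction_within(h: ErrorHistogram, k: int = 3) -> int:
    """Percentage of observations with |error| <= k, to the nearest integer.

    ``k`` must not exceed 6: beyond that the open bins would turn the
    fraction into a bound rather than an exact value.
    """
    if h.n == 0:
        raise ValueError("empty histogram")
    if not (1 <= k <= 6):
        raise ValueError("k must be in 1..6 (open bins start at |error| = 7)")
    inside = sum(h.counts[7 - k : 7 + k + 1])
    return int(math.floor(100.0 * inside / h.n + 0.5))


def paired_stats(obs) -> dict:
    """Pearson r, mean/variance of errors, and a two-sided paired t-test.

    Returns ``{"r", "mean_error", "error_variance", "p_value"}``; ``r`` is
    NaN when either margin has zero variance (correlation undefined).
    Requires at least 3 pairs.
    """
    obs = list(obs)
    if len(obs) < 3:
        raise ValueError("need >= 3 paired observations")
    truth = np.array([t for t, _ in obs], dtype=float)
    est = np.array([e for _, e in obs], dtype=float)
    errors = est - truth
    if np.ptp(truth) == 0 or np.ptp(est) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(truth, est).statistic)
    t = stats.ttest_rel(est, truth)
    return {
        "r": r,
        "mean_error": float(errors.mean()),
        "error_variance": float(errors.var(ddof=1)) if len(obs) > 1 else 0.0,
        "p_value": float(t.pvalue),
    }


def group_average_error(obs, group_size: int, reps: int, seed: int) -> dict:
    """Error statistics of group-averaged counts.

    Repeatedly (``reps`` times) draws ``group_size`` hills without
    replacement, averages truth and estimate within the group, and collects
    the group-average error.  Returns the mean absolute group error and the
    standard deviation of group errors.  For independent per-hill errors the
    SD shrinks as 1/sqrt(group_size); averaging whole plots therefore
    stabilises the estimate even when single hills are noisy.
    """
    obs = list(obs)
    n = len(obs)
    if group_size < 1 or reps < 1:
        raise ValueError("group_size and reps must be >= 1")
    if group_size > n:
        raise ValueError(f"group_size {group_size} exceeds {n} observations")
    rng = np.random.default_rng(seed)
    truth = np.array([t for t, _ in obs], dtype=float)
    est = np.array([e for _, e in obs], dtype=float)
    errs = np.empty(reps)
    for i in range(reps):
        idx = rng.choice(n, size=group_size, replace=False)
        errs[i] = est[idx].mean() - truth[idx].mean()
    return {
        "mean_abs_error": float(np.abs(errs).mean()),
        "error_sd": float(errs.std(ddof=0)),
    }


def field_histogram_keys() -> list[tuple[str, str]]:
    """The nine packaged (comparison, date) histogram identifiers."""
    return [(c, d) for c in _COMPARISONS for d in _DATES]


def load_field_histogram(comparison: str, date: str) -> ErrorHistogram:
    """Load one packaged field-campaign error histogram.

    ``comparison`` is one of ``true_manual`` (true tiller number vs manual
    leaf-tip count), ``manual_auto`` (manual vs automatic leaf-tip count) or
    ``true_auto`` (true tiller number vs automatic count); ``date`` is one
    of ``jul03``, ``jul23``, ``aug07``.
    """
    if comparison not in _COMPARISONS or date not in _DATES:
        raise KeyError(f"unknown histogram {comparison}/{date}")
    text = (
        resources.files("tillersight")
        .joinpath(f"data/field_histograms/{comparison}_{date}.tsv")
        .read_text()
    )
    counts: dict[str, int] = {}
    for line in text.strip().splitlines()[1:]:
        label, value = line.split("\t")
        counts[label] = int(value)
    return ErrorHistogram(tuple(counts[lbl] for lbl in BIN_LABELS))
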