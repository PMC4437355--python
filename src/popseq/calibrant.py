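"""Per-run multiplicity threshold ("calibrant") separating noise from signal.

Sequencing errors generate k-mers that are each seen only a handful of times,
while genomic k-mers recur in proportion to coverage, so the histogram of
observation multiplicities is typically bimodal: an error mode at low
multiplicity and a coverage mode near the per-k-mer read depth.  The calibrant
is the multiplicity cutoff between the two — retain k-mers observed >= t times.
Two estimators are provided: ``valley`` (default) finds the first local minimum
of the smoothed histogram between the two modes; ``poisson_mix`` fits a
two-component Poisson mixture by EM and returns the smallest multiplicity at
which the posterior odds favor the signal component.  The threshold is
recomputed per run because both modes move with coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .kmer_index import KmerMultiset, KmerSet, KmerSignature

logger = logging.getLogger("popseq")

__all__ = [
    "MultiplicityHistogram",
    "CalibrantThreshold",
    "CalibrantMethod",
    "multiplicity_histogram",
    "fit_calibrant",
    "apply_threshold",
    "signal_noise_curve",
]


class CalibrantMethod(str, Enum):
    VALLEY = "valley"
    POISSON_MIX = "poisson_mix"
    FIXED = "fixed"


@dataclass(frozen=True)
class MultiplicityHistogram:
    """Map multiplicity -> number of distinct canonical k-mers seen that often."""

    bins: Mapping[int, int]
    n_distinct: int

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.bins):
            raise ValueError("multiplicities must be >= 1")
        if sum(self.bins.values()) != self.n_distinct:
            raise ValueError("bin values must sum to n_distinct")

    @property
    def n_kmers_total(self) -> int:
        return sum(m * c for m, c in self.bins.items())

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.bins.items())
        return pd.DataFrame(items, columns=["multiplicity", "count"])

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CalibrantThreshold:
    """Retain k-mers with observation multiplicity >= t."""

    t: int
    noise_mean: float | None = None
    signal_mean: float | None = None
    method: CalibrantMethod = CalibrantMethod.VALLEY
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("threshold t must be >= 1")
        if (
            self.noise_mean is not None
            and self.signal_mean is not None
            and not self.noise_mean < self.signal_mean
        ):
            raise ValueError("noise_mean must be below signal_mean")

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "noise_mean": self.noise_mean,
            "signal_mean": self.signal_mean,
            "method": self.method.value,
            "degenerate": self.degenerate,
        }


def multiplicity_histogram(ms: KmerMultiset) -> MultiplicityHistogram:
    """Tally how many distinct k-mers were observed at each multiplicity.

    Conservation: sum over bins of multiplicity * count equals the total number
    of counted windows.
    """
    if ms.n_distinct == 0:
        raise ValueError("multiplicity histogram of an empty multiset is undefined")
    values, counts = np.unique(ms.totals, return_counts=True)
    bins = {int(m): int(c) for m, c in zip(values, counts)}
    return MultiplicityHistogram(bins=bins, n_distinct=ms.n_distinct)


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    if window <= 1 or a.size < 3:
        return a.astype(float)
    half = window // 2
    out = np.empty(a.size, dtype=float)
    for i in range(a.size):
        lo, hi = max(0, i - half), min(a.size, i + half + 1)
        out[i] = a[lo:hi].mean()
    return out


def _dense_counts(hist: MultiplicityHistogram) -> np.ndarray:
    """counts[m] for m = 0..max multiplicity (index 0 unused)."""
    m_max = max(hist.bins)
    dense = np.zeros(m_max + 1, dtype=float)
    for m, c in hist.bins.items():
        dense[m] = c
    return dense


def _side_means(dense: np.ndarray, t: int) -> tuple[float | None, float | None]:
    m = np.arange(dense.size)
    below, above = (m >= 1) & (m < t), m >= t
    noise = float((m[below] * dense[below]).sum() / dense[below].sum()) if dense[below].sum() else None
    signal = float((m[above] * dense[above]).sum() / dense[above].sum()) if dense[above].sum() else None
    return noise, signal


def _fit_valley(hist: MultiplicityHistogram, smooth_window: int) -> CalibrantThreshold:
    dense = _dense_counts(hist)
    m_max = dense.size - 1
    if len(hist.bins) == 1:
        logger.warning("calibrant: single-bin histogram, degenerate threshold t=1")
        return CalibrantThreshold(t=1, method=CalibrantMethod.VALLEY, degenerate=True)
    s = np.concatenate(([0.0], _smooth(dense[1:], smooth_window)))  # s[m] for m>=1
    if m_max < 3 or s[1] < s[2]:
        # No error mode at low multiplicity (e.g. error-free data): nothing to reject.
        logger.warning("calibrant: no low-multiplicity noise mode detected, t=1")
        noise, signal = _side_means(dense, 1)
        return CalibrantThreshold(
            t=1, noise_mean=noise, signal_mean=signal, method=CalibrantMethod.VALLEY
        )
    # First rise after the initial descent marks the far side of the valley.
    rise = None
    for m in range(2, m_max + 1):
        if s[m] > s[m - 1]:
            rise = m
            break
    if rise is None:
        logger.warning("calibrant: unimodal histogram, t=1")
        noise, signal = _side_means(dense, 1)
        return CalibrantThreshold(
            t=1, noise_mean=noise, signal_mean=signal, method=CalibrantMethod.VALLEY
        )
    region = s[2:rise]  # candidate valley positions 2..rise-1
    vmin = region.min()
    t = 2 + int(np.flatnonzero(region == vmin)[0])  # ties -> smaller t
    noise, signal = _side_means(dense, t)
    return CalibrantThreshold(
        t=t, noise_mean=noise, signal_mean=signal, method=CalibrantMethod.VALLEY
    )


def _fit_poisson_mix(
    hist: MultiplicityHistogram, max_iter: int = 500, tol: float = 1e-10
) -> CalibrantThreshold:
    if len(hist.bins) == 1:
        logger.warning("calibrant: single-bin histogram, degenerate threshold t=1")
        return CalibrantThreshold(t=1, method=CalibrantMethod.POISSON_MIX, degenerate=True)
    m = np.array(sorted(hist.bins), dtype=float)
    w = np.array([hist.bins[int(v)] for v in m], dtype=float)
    mean = float((m * w).sum() / w.sum())
    lam1, lam2 = max(0.5, 0.25 * mean), max(2.0 * mean, 2.0)
    pi1 = 0.5
    for _ in range(max_iter):
        logp1 = np.log(pi1 + 1e-300) + poisson.logpmf(m, lam1)
        logp2 = np.log(1 - pi1 + 1e-300) + poisson.logpmf(m, lam2)
        mx = np.maximum(logp1, logp2)
        r1 = np.exp(logp1 - mx)
        r2 = np.exp(logp2 - mx)
        g1 = r1 / (r1 + r2)
        new_pi1 = float((g1 * w).sum() / w.sum())
        new_lam1 = float((g1 * w * m).sum() / max((g1 * w).sum(), 1e-300))
        new_lam2 = float(((1 - g1) * w * m).sum() / max(((1 - g1) * w).sum(), 1e-300))
        if (
            abs(new_pi1 - pi1) < tol
            and abs(new_lam1 - lam1) < tol
            and abs(new_lam2 - lam2) < tol
        ):
            pi1, lam1, lam2 = new_pi1, new_lam1, new_lam2
            break
        pi1, lam1, lam2 = new_pi1, new_lam1, new_lam2
    if lam1 > lam2:
        lam1, lam2, pi1 = lam2, lam1, 1 - pi1
    # Smallest multiplicity at which posterior odds favor the signal component.
    grid = np.arange(1, int(max(hist.bins)) + 2)
    signal_wins = (np.log(1 - pi1 + 1e-300) + poisson.logpmf(grid, lam2)) >= (
        np.log(pi1 + 1e-300) + poisson.logpmf(grid, lam1)
    )
    t = int(grid[signal_wins][0]) if signal_wins.any() else 1
    if lam1 >= lam2 - 1e-12:
        logger.warning("calibrant: mixture collapsed to one component, t=1")
        return CalibrantThreshold(t=1, method=CalibrantMethod.POISSON_MIX, degenerate=True)
    return CalibrantThreshold(
        t=max(t, 1),
        noise_mean=lam1,
        signal_mean=lam2,
        method=CalibrantMethod.POISSON_MIX,
    )


def fit_calibrant(
    hist: MultiplicityHistogram,
    method: CalibrantMethod | str = CalibrantMethod.VALLEY,
    smooth_window: int = 3,
    fixed_t: int | None = None,
) -> CalibrantThreshold:
    """Estimate the noise/signal multiplicity cutoff from a histogram.

    ``valley``: first local minimum of the smoothed histogram between the error
    mode and the coverage mode, ties broken toward the smaller multiplicity;
    degenerate or unimodal histograms yield t = 1 with a logged warning.
    ``poisson_mix``: two-component Poisson mixture via EM.  ``fixed``: take
    ``fixed_t`` as given.
    """
    method = CalibrantMethod(method)
    if method is CalibrantMethod.FIXED:
        if fixed_t is None:
            raise ValueError("fixed method requires fixed_t")
        return CalibrantThreshold(t=fixed_t, method=CalibrantMethod.FIXED)
    if method is CalibrantMethod.VALLEY:
        return _fit_valley(hist, smooth_window)
    return _fit_poisson_mix(hist)


def apply_threshold(ms: KmerMultiset, cal: CalibrantThreshold) -> KmerSet:
    """Retain the canonical k-mers observed at least ``cal.t`` times.

    Monotone: raising t never adds k-mers.
    """
    keep = ms.totals >= cal.t
    return KmerSet(k=ms.k, codes=ms.codes[keep])


def signal_noise_curve(
    ms: KmerMultiset, truth: KmerSignature | KmerSet, t_max: int
) -> pd.DataFrame:
    """Signal/noise retention and SNR as the multiplicity threshold sweeps 1..t_max.

    At each t, signal = retained k-mers in the truth signature, noise = retained
    k-mers outside it.  Fractions are relative to the t = 1 (unfiltered) sets;
    SNR with zero retained noise is reported as +inf (0/0 as +inf too: nothing
    retained, nothing wrong).
    """
    if len(truth) == 0:
        raise ValueError("truth signature must be non-empty")
    in_truth = truth.member_mask(ms.codes)
    signal0 = int(in_truth.sum())
    noise0 = int((~in_truth).sum())
    rows = []
    for t in range(1, t_max + 1):
        keep = ms.totals >= t
        n_signal = int((keep & in_truth).sum())
        n_noise = int((keep & ~in_truth).sum())
        rows.append(
            {
                "t": t,
                "signal_retained": n_signal,
                "noise_retained": n_noise,
                "signal_retained_fraction": n_signal / signal0 if signal0 else 0.0,
                "noise_retained_fraction": n_noise / noise0 if noise0 else 0.0,
                "snr": (n_signal / n_noise) if n_noise else float("inf"),
            }
        )
    return pd.DataFrame(rows)
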