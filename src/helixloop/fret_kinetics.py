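"""Cyclization kinetics from smFRET population histograms.

Analysis chain: per-frame FRET efficiency E = I_A / (I_D + I_A) ->
per-timepoint efficiency histograms -> least-squares two-Gaussian fit of
each histogram -> looped fraction A_H / (A_H + A_L) from the component
areas -> nonlinear fit of f(t) = A (1 - e^{-R t}) -> looping rate R and
looping time 1/R, with construct-to-construct fold-change comparison.

Mixture fitting is least squares on binned counts (the histograms are the
measured objects), not maximum likelihood on raw efficiencies.  Component
areas are computed analytically as amplitude * sigma * sqrt(2*pi), so the
looped fraction is bin-width independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Histogram",
    "GaussianMixtureFit",
    "KineticsFit",
    "FitFailureError",
    "fret_efficiency",
    "build_histogram",
    "fit_two_gaussians",
    "looped_fraction",
    "fit_looping_kinetics",
    "compare_constructs",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class FitFailureError(RuntimeError):
    """Raised when a fit does not converge or is degenerate.

    ``diagnostics`` carries the best parameters found (if any) and the
    reason for failure."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class Histogram:
    """Counts over uniform bins spanning [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class GaussianMixtureFit:
    """Two-Gaussian histogram fit; components ordered so mu_L < mu_H.

    ``A_L``/``A_H`` are the areas under the low- and high-FRET component
    curves; ``degenerate`` flags strongly overlapping components."""

    A_L: float
    mu_L: float
    sigma_L: float
    A_H: float
    mu_H: float
    sigma_H: float
    rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class KineticsFit:
    """Fit of f(t) = A (1 - e^{-R t}).

    ``A`` is the plateau looped fraction, ``R`` the looping rate per
    minute, ``looping_time`` = 1/R minutes."""

    A: float
    R: float
    se_A: float
    se_R: float
    residuals: np.ndarray

    @property
    def looping_time(self) -> float:
        return 1.0 / self.R

    @property
    def se_looping_time(self) -> float:
        # first-order propagation through 1/R
        return self.se_R / self.R**2


def fret_efficiency(I_D, I_A):
    """FRET efficiency E = I_A / (I_D + I_A), elementwise."""
    I_D = np.asarray(I_D, dtype=float)
    I_A = np.asarray(I_A, dtype=float)
    if np.any(I_D < 0) or np.any(I_A < 0):
        raise ValueError("intensities must be non-negative")
    total = I_D + I_A
    if np.any(total == 0):
        raise ValueError("FRET efficiency undefined where I_D + I_A = 0")
    out = I_A / total
    return float(out) if out.ndim == 0 else out


def build_histogram(efficiencies, bin_width: float = 0.02) -> Histogram:
    """Bin efficiencies into uniform bins on [0, 1]; total count preserved.

    Values of exactly 1.0 land in the last bin (numpy's closed right edge
    on the final bin)."""
    eff = np.asarray(efficiencies, dtype=float)
    if not 0.0 < bin_width <= 1.0:
        raise ValueError("bin_width must be in (0, 1]")
    if eff.size and (eff.min() < 0.0 or eff.max() > 1.0):
        raise ValueError("efficiencies must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(eff, bins=edges)
    return Histogram(bin_edges=edges, counts=counts)


def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


def _initial_peaks(
    centers: np.ndarray, counts: np.ndarray, min_separation: float = 0.2
) -> tuple[float, float]:
    """Initialization: the two highest local maxima of the (lightly
    smoothed) counts that are at least ``min_separation`` apart,
    tie-broken toward the extremes of [0, 1].  When no second separated
    peak exists (single-population data) the second component starts at
    the opposite extreme."""
    c = counts.astype(float)
    if c.size >= 5:
        c = np.convolve(c, np.ones(3) / 3.0, mode="same")
    interior = (c[1:-1] >= c[:-2]) & (c[1:-1] >= c[2:]) & (c[1:-1] > 0)
    idx = np.flatnonzero(interior) + 1
    if idx.size:
        order = sorted(idx, key=lambda i: (-c[i], -abs(centers[i] - 0.5)))
        first = centers[order[0]]
        second = next(
            (centers[i] for i in order[1:] if abs(centers[i] - first) >= min_separation),
            None,
        )
        if second is None:
            second = 0.85 if first < 0.5 else 0.15
        return (min(first, second), max(first, second))
    return (0.15, 0.85)


def fit_two_gaussians(hist: Histogram) -> GaussianMixtureFit:
    """Least-squares fit of the sum of two Gaussians to bin counts.

    Areas are amplitude * sigma * sqrt(2*pi).  A fit is flagged/raised as
    degenerate when the means overlap within 2 * max(sigma) while both
    components carry non-negligible area (>= 2% of the total each): two
    such components do not represent distinct populations.
    """
    counts = np.asarray(hist.counts, dtype=float)
    centers = hist.centers
    if np.count_nonzero(counts) < 8:
        raise FitFailureError(
            "histogram must have >= 8 non-empty bins",
            {"non_empty_bins": int(np.count_nonzero(counts))},
        )
    m_lo, m_hi = _initial_peaks(centers, counts)
    # start each amplitude from the observed counts at its peak, so an
    # absent population starts (and stays) near zero amplitude
    amp_lo = max(float(counts[np.argmin(np.abs(centers - m_lo))]), 1.0)
    amp_hi = max(float(counts[np.argmin(np.abs(centers - m_hi))]), 1.0)
    p0 = [amp_lo, m_lo, 0.08, amp_hi, m_hi, 0.08]
    free_bounds = (
        [0.0, 0.0, 1e-4, 0.0, 0.0, 1e-4],
        [np.inf, 1.0, 0.5, np.inf, 1.0, 0.5],
    )
    # second stage when the free fit fails or degenerates: confine the
    # components to the low-FRET ([0, 0.5)) and high-FRET ([0.5, 1]) halves
    # of the efficiency range, the structure of a looping assay with
    # well-separated unlooped/looped populations.  One component may then
    # carry ~zero amplitude, which is the honest answer for a
    # single-population histogram.
    mid = 0.5
    lo_init = min(m_lo, mid - 1e-3)
    hi_init = m_hi if m_hi >= mid else 1.0 - lo_init
    amp_hi2 = max(float(counts[np.argmin(np.abs(centers - hi_init))]), 1.0)
    split_bounds = (
        [0.0, 0.0, 1e-4, 0.0, mid, 1e-4],
        [np.inf, mid, 0.5, np.inf, 1.0, 0.5],
    )
    split_p0 = [amp_lo, lo_init, 0.08, amp_hi2, hi_init, 0.08]

    fit = None
    failure: Exception | None = None
    for p_init, bounds in ((p0, free_bounds), (split_p0, split_bounds)):
        try:
            popt, _ = curve_fit(
                _two_gaussians, centers, counts, p0=p_init, bounds=bounds,
                maxfev=20000,
            )
        except RuntimeError as exc:
            failure = exc
            continue
        a1, m1, s1, a2, m2, s2 = popt
        if m1 > m2:
            a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
        area_l = a1 * s1 * SQRT_2PI
        area_h = a2 * s2 * SQRT_2PI
        rss = float(np.sum((_two_gaussians(centers, *popt) - counts) ** 2))
        total = area_l + area_h
        degenerate = bool(
            abs(m2 - m1) < 2.0 * max(s1, s2)
            and total > 0
            and min(area_l, area_h) / total >= 0.02
        )
        fit = GaussianMixtureFit(
            A_L=float(area_l),
            mu_L=float(m1),
            sigma_L=float(s1),
            A_H=float(area_h),
            mu_H=float(m2),
            sigma_H=float(s2),
            rss=rss,
            degenerate=degenerate,
        )
        if not degenerate:
            return fit
    if fit is not None:
        raise FitFailureError(
            f"degenerate fit: means {fit.mu_L:.3f}/{fit.mu_H:.3f} overlap "
            f"within 2*sigma ({max(fit.sigma_L, fit.sigma_H):.3f})",
            {"fit": fit},
        )
    raise FitFailureError(f"two-Gaussian fit did not converge: {failure}")


def looped_fraction(fit: GaussianMixtureFit) -> float:
    """Looped population fraction A_H / (A_H + A_L)."""
    total = fit.A_H + fit.A_L
    if total <= 0:
        raise ValueError("looped fraction undefined: both component areas are zero")
    return fit.A_H / total


def _saturating_exponential(t, A, R):
    return A * (1.0 - np.exp(-R * t))


def fit_looping_kinetics(timepoints, fractions) -> KineticsFit:
    """Nonlinear least squares for f(t) = A (1 - e^{-R t}).

    ``timepoints`` in minutes, ``fractions`` in [0, 1].  Requires >= 4
    timepoints.  Raises :class:`FitFailureError` when the data carry no
    looping signal (all fractions ~ 0) or the optimizer fails.
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 timepoints to fit looping kinetics")
    if t.size != f.size:
        raise ValueError("timepoints and fractions must have equal length")
    if np.all(f < 1e-3):
        raise FitFailureError(
            "all looped fractions are ~0; no looping signal to fit",
            {"max_fraction": float(f.max(initial=0.0))},
        )
    A0 = min(max(float(f.max()), 1e-3), 1.0)
    # crude rate guess from the earliest timepoint that reaches half of A0
    above = t[(f >= 0.5 * A0) & (t > 0)]
    R0 = np.log(2.0) / float(above.min()) if above.size else 0.05
    try:
        popt, pcov = curve_fit(
            _saturating_exponential,
            t,
            f,
            p0=[A0, R0],
            bounds=([0.0, 1e-8], [1.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"kinetics fit did not converge: {exc}") from exc
    A, R = popt
    if A <= 0 or R <= 0:
        raise FitFailureError(
            "kinetics fit degenerate (non-positive A or R)",
            {"A": float(A), "R": float(R)},
        )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = f - _saturating_exponential(t, A, R)
    return KineticsFit(
        A=float(A), R=float(R), se_A=float(se[0]), se_R=float(se[1]), residuals=resid
    )


def compare_constructs(
    fits: dict[str, list[KineticsFit]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize looping times per construct and their pairwise ratios.

    Returns ``(summary, ratios)``: ``summary`` has one row per construct
    with the mean looping time (minutes) over replicates and its standard
    error SD/sqrt(n) (NaN for a single replicate — undefined, not zero);
    ``ratios`` has one row per ordered construct pair with the ratio of
    mean looping times and a delta-method propagated SE.
    """
    rows = []
    for name, replicate_fits in fits.items():
        if not replicate_fits:
            raise ValueError(f"construct {name!r} has no replicate fits")
        times = np.array([fit.looping_time for fit in replicate_fits])
        n = times.size
        se = float(times.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            {
                "construct": name,
                "n_replicates": n,
                "mean_looping_time": float(times.mean()),
                "se_looping_time": se,
            }
        )
    summary = pd.DataFrame(rows).set_index("construct")

    ratio_rows = []
    for a, b in itertools.permutations(summary.index, 2):
        ma, sa = summary.loc[a, ["mean_looping_time", "se_looping_time"]]
        mb, sb = summary.loc[b, ["mean_looping_time", "se_looping_time"]]
        ratio = ma / mb
        if np.isnan(sa) or np.isnan(sb):
            se_ratio = np.nan
        else:
            se_ratio = abs(ratio) * np.sqrt((sa / ma) ** 2 + (sb / mb) ** 2)
        ratio_rows.append(
            {
                "numerator": a,
                "denominator": b,
                "looping_time_ratio": float(ratio),
                "se_ratio": float(se_ratio) if not np.isnan(se_ratio) else np.nan,
            }
        )
    ratios = pd.DataFrame(ratio_rows)
    return summary, ratios
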