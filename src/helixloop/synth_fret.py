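"""Synthetic single-molecule cyclization (smFRET) data generator.

Emulates the statistical structure of a surface-tethered cyclization
assay: at t = 0 a high-salt buffer is added, after which each molecule
independently loops at rate ``R`` (per minute).  Looping is treated as
irreversible, and a fraction ``1 - A`` of molecules never loops, which is
the mechanistic reading of a plateau looped fraction ``A < 1``.  The
expected looped fraction at time t is therefore

    f(t) = A * (1 - exp(-R * t)).

At each timepoint an independent cross-section of ``n_molecules``
molecules is imaged; a molecule's apparent FRET efficiency is drawn from
a low-FRET Gaussian (unlooped) or a high-FRET Gaussian (looped),
truncated to [0, 1].  Single traces are simulated at the camera frame
time (default 100 ms) with Gaussian intensity noise on donor/acceptor
counts at fixed total intensity.

The generator is what the kinetics pipeline is validated against; it does
not model photobleaching, spectral crosstalk, or camera noise physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CyclizationModel",
    "HistogramSeries",
    "FretTrace",
    "simulate_population_histograms",
    "simulate_trace",
]

DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 61, 10))


@dataclass(frozen=True)
class CyclizationModel:
    """Generative model of one cyclization experiment.

    Rates are per minute; times are minutes since high-salt addition.
    Defaults mirror a typical short-duplex experiment: ~2500 molecules per
    timepoint, timepoints every 10 min out to an hour, well-separated
    unlooped/looped FRET populations.
    """

    R: float = 0.05
    A: float = 0.8
    mu_low: float = 0.15
    sigma_low: float = 0.08
    mu_high: float = 0.85
    sigma_high: float = 0.08
    n_molecules: int = 2500
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    total_intensity: float = 1000.0
    intensity_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_low < self.mu_high <= 1.0):
            raise ValueError("require 0 <= mu_low < mu_high <= 1")
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ValueError("sigma_low and sigma_high must be positive")
        if self.R <= 0:
            raise ValueError("looping rate R must be positive")
        if not 0.0 < self.A <= 1.0:
            raise ValueError("plateau fraction A must be in (0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    def looped_fraction(self, t: np.ndarray | float) -> np.ndarray | float:
        """Expected looped fraction f(t) = A (1 - e^{-R t})."""
        return self.A * (1.0 - np.exp(-self.R * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class HistogramSeries:
    """Per-timepoint FRET-efficiency histograms on shared bins.

    ``counts[k]`` are the bin counts at ``timepoints[k]``;
    ``looped_counts`` holds the latent number of looped molecules per
    timepoint (ground truth for recovery checks).
    """

    timepoints: np.ndarray  # minutes, shape (T,)
    bin_edges: np.ndarray  # shape (B + 1,), spanning [0, 1]
    counts: np.ndarray  # shape (T, B), ints
    looped_counts: np.ndarray  # shape (T,), ints

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        edges = np.asarray(self.bin_edges)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclass(frozen=True)
class FretTrace:
    """A single-molecule donor/acceptor intensity trace.

    ``state_path`` is 0 (unlooped) or 1 (looped) per frame and is
    monotone non-decreasing: looping is irreversible.
    ``loop_time`` is the latent looping time in seconds (``None`` for a
    non-looper); it may fall beyond the end of the trace."""

    molecule_id: int
    times: np.ndarray  # s
    I_D: np.ndarray
    I_A: np.ndarray
    state_path: np.ndarray
    loop_time: float | None

    def __post_init__(self) -> None:
        if np.any(self.I_D < 0) or np.any(self.I_A < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(np.diff(self.state_path) < 0):
            raise ValueError("state path must be monotone (irreversible looping)")


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, size: int
) -> np.ndarray:
    """Gaussian draws rejected outside [0, 1] (efficiency support)."""
    out = rng.normal(mu, sigma, size)
    bad = (out < 0.0) | (out > 1.0)
    while np.any(bad):
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = (out < 0.0) | (out > 1.0)
    return out


def simulate_population_histograms(
    model: CyclizationModel, bin_width: float = 0.02
) -> HistogramSeries:
    """Simulate per-timepoint FRET-efficiency histograms.

    Each timepoint is an independent cross-section: every one of
    ``model.n_molecules`` molecules is looped with probability
    ``A (1 - e^{-R t})``, then its efficiency is drawn from the state's
    truncated Gaussian.  Deterministic given ``model.seed``.
    """
    if len(model.timepoints) == 0:
        raise ValueError("model must define at least one timepoint")
    rng = np.random.default_rng(model.seed)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    times = np.asarray(model.timepoints, dtype=float)
    counts = np.zeros((len(times), n_bins), dtype=int)
    looped = np.zeros(len(times), dtype=int)
    for k, t in enumerate(times):
        p = float(model.looped_fraction(t))
        is_looped = rng.random(model.n_molecules) < p
        n_hi = int(is_looped.sum())
        eff = np.empty(model.n_molecules)
        eff[~is_looped] = _truncated_normal(
            rng, model.mu_low, model.sigma_low, model.n_molecules - n_hi
        )
        eff[is_looped] = _truncated_normal(rng, model.mu_high, model.sigma_high, n_hi)
        counts[k], _ = np.histogram(eff, bins=edges)
        looped[k] = n_hi
    return HistogramSeries(
        timepoints=times, bin_edges=edges, counts=counts, looped_counts=looped
    )


def simulate_trace(
    model: CyclizationModel,
    duration: float,
    dt: float = 0.1,
    molecule_id: int = 0,
    rng: np.random.Generator | None = None,
) -> FretTrace:
    """Simulate one molecule's intensity trace at frame time ``dt`` (s).

    With probability ``1 - A`` the molecule is a non-looper; otherwise its
    looping time is exponential with rate ``R`` (converted from per-minute
    to per-second).  Frames before the transition sample the unlooped
    efficiency, frames at/after it the looped efficiency; donor/acceptor
    intensities split the (noisy) total intensity by efficiency.
    """
    if not duration > dt > 0:
        raise ValueError("require duration > dt > 0")
    if rng is None:
        rng = np.random.default_rng(model.seed + molecule_id)
    n_frames = int(np.floor(duration / dt))
    times = np.arange(n_frames) * dt

    rate_per_s = model.R / 60.0
    if rng.random() < model.A:
        loop_time: float | None = float(rng.exponential(1.0 / rate_per_s))
    else:
        loop_time = None

    state = np.zeros(n_frames, dtype=int)
    if loop_time is not None and loop_time < times[-1] + dt:
        state[times >= loop_time] = 1

    mu = np.where(state == 1, model.mu_high, model.mu_low)
    sigma = np.where(state == 1, model.sigma_high, model.sigma_low)
    if model.intensity_noise > 0:
        eff = np.clip(rng.normal(mu, sigma), 0.0, 1.0)
        total = np.maximum(
            rng.normal(model.total_intensity, model.intensity_noise, n_frames), 0.0
        )
    else:
        eff = mu.astype(float)
        total = np.full(n_frames, model.total_intensity)
    I_A = eff * total
    I_D = (1.0 - eff) * total
    return FretTrace(
        molecule_id=molecule_id,
        times=times,
        I_D=I_D,
        I_A=I_A,
        state_path=state,
        loop_time=loop_time,
    )
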