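"""Shared fixtures and pipeline helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import helixloop as hl
from helixloop.fret_kinetics import Histogram


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def rdh53_duplex():
    return hl.construct_duplex("C-DNA/G-RNA RDH-53")


def recover_kinetics(model: hl.CyclizationModel) -> hl.KineticsFit:
    """Full analysis chain on simulated data: histograms -> two-Gaussian
    fits -> looped fractions -> saturating-exponential kinetics fit."""
    series = hl.simulate_population_histograms(model)
    fractions = []
    for counts in series.counts:
        fit = hl.fit_two_gaussians(Histogram(bin_edges=series.bin_edges, counts=counts))
        fractions.append(hl.looped_fraction(fit))
    return hl.fit_looping_kinetics(series.timepoints, fractions)


def random_frame(rng: np.random.Generator) -> hl.BpFrame:
    from scipy.spatial.transform import Rotation

    return hl.BpFrame(
        origin=rng.normal(0.0, 10.0, 3),
        triad=Rotation.random(random_state=rng).as_matrix(),
    )
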