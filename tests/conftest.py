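"""Shared fixtures: tiny protocols and simulated data, generated at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from t1shot import (ReconConfig, get_protocol, make_t1_phantom,
                    coil_profiles, build_schedule, analytic_kspace)


@pytest.fixture(scope="session")
def head1_tiny_seq():
    """Single-slice head protocol shrunk to a 32-pixel matrix."""
    return get_protocol("head1", 1 / 12)


@pytest.fixture(scope="session")
def head3_tiny_seq():
    return get_protocol("head3", 1 / 12)


@pytest.fixture(scope="session")
def phantom_default():
    return make_t1_phantom()


@pytest.fixture(scope="session")
def coils_default():
    return coil_profiles(n_coils=4)


@pytest.fixture(scope="session")
def kdata_tiny(head1_tiny_seq, phantom_default, coils_default):
    """Noiseless analytic k-space of the tiny single-slice protocol."""
    sched = build_schedule(head1_tiny_seq)
    return analytic_kspace(phantom_default, coils_default, sched,
                           head1_tiny_seq)


@pytest.fixture(scope="session")
def fast_config():
    """Small-budget reconstruction settings for smoke-level pipeline tests."""
    return ReconConfig(n_fista_start=15, n_fista_max=60, power_iters=6)


def make_single_compartment_kdata(n=32, t1_ms=800.0, n_spokes=64,
                                  n_coils=2, binned=4):
    """Uniform-disk phantom data for parameter-recovery tests."""
    from t1shot import PhantomDef
    from t1shot.phantom import Ellipse

    seq = dataclasses.replace(
        get_protocol("head1"), base_resolution=n, readout_samples=2 * n,
        spokes_per_slice=n_spokes, binned_spokes=binned)
    ph = PhantomDef(compartments=(
        Ellipse(0.0, 0.0, 0.35, 0.35, 0.0, 1.0 + 0.0j, t1_ms),))
    coils = coil_profiles(n_coils=n_coils)
    sched = build_schedule(seq)
    return analytic_kspace(ph, coils, sched, seq), seq, ph
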