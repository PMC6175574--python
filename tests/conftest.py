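"""Shared fixtures: canonical schemes/rates and simulated k_obs datasets.

The expensive simulate -> fit pipelines (dissociation-rate curves, the
k_obs-versus-substrate surfaces, the global-fit trace sets) are
session-scoped so that module tests and the acceptance suite share one
computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gltkin as g
from gltkin.relaxation import (
    RelaxationTrace,
    make_binding_experiment,
    make_dissociation_experiment,
)
from gltkin.synthetic import DEFAULT_STOCK, NoiseModel, generate_trace

warnings.filterwarnings("ignore", message="lsoda")

#: Na+ grid (M) of the plateau-rate experiments
CS_NA_GRID = (0.5e-3, 1e-3, 2e-3, 4e-3, 8e-3)
#: substrate grid (M): the published 0.01-2 mM set extended to the plateau
CS_ASP_GRID = tuple(
    x * 1e-3 for x in (0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
)


@pytest.fixture(scope="session")
def asp_scheme():
    return g.build_scheme("P11W_ASP")


@pytest.fixture(scope="session")
def asp_rates():
    return g.canonical_rate_set("P11W_ASP")


@pytest.fixture(scope="session")
def tboa_scheme():
    return g.build_scheme("P11W_TBOA")


@pytest.fixture(scope="session")
def tboa_rates():
    return g.canonical_rate_set("P11W_TBOA")


@pytest.fixture(scope="session")
def fm_scheme():
    return g.build_scheme("FM_ASP")


@pytest.fixture(scope="session")
def fm_rates():
    return g.canonical_rate_set("FM_ASP")


@pytest.fixture(scope="session")
def dissociation_kobs(asp_scheme, asp_rates):
    """Noise-free k_obs,d over final Na+ 50 uM - 1 mM (dilution protocol)."""
    na_grid = np.geomspace(50e-6, 1e-3, 10)
    return g.kobs_surface(
        asp_scheme, asp_rates, na_grid, None, direction="dissociation"
    )


@pytest.fixture(scope="session")
def cs_binding_data(asp_scheme, asp_rates, dissociation_kobs):
    """Per-Na+ (substrate, k_obs) tables plus per-Na+ k_off from the n=2 fit."""
    hill = g.HillDissociationModel(
        dissociation_kobs["na"].to_numpy(), dissociation_kobs["k_obs"].to_numpy()
    ).fit(n=2)
    data, koffs = {}, {}
    for na in CS_NA_GRID:
        surf = g.kobs_surface(
            asp_scheme, asp_rates, [na], CS_ASP_GRID, direction="binding"
        )
        data[na] = (surf["ligand"].to_numpy(), surf["k_obs"].to_numpy())
        koffs[na] = float(g.kobs_dissociation_hill(hill.params, na))
    return data, koffs


def _thin(trace: RelaxationTrace, n: int = 80) -> RelaxationTrace:
    idx = np.linspace(0, len(trace.times) - 1, n).astype(int)
    return RelaxationTrace(trace.times[idx], trace.signal[idx], trace.metadata)


def make_recovery_traces(scheme, rates, noise_sd, seed, points_per_trace=80):
    """Reduced global-fit dataset: 9 binding + 3 dissociation traces.

    A scaled-down stand-in for the 58-binding/21-dissociation protocol,
    spanning the same Na+ contrast (1, 3.6, 8 mM) and substrate range.
    """
    rng = np.random.default_rng(seed)
    traces = []
    for na in (1e-3, 3.6e-3, 8e-3):
        for asp in (5e-5, 2.5e-4, 1e-3):
            exp = make_binding_experiment(1e-6, na, asp, scheme, rates)
            traces.append(
                generate_trace(
                    exp, scheme, rates, NoiseModel(noise_sd, int(rng.integers(2**31)))
                )
            )
    for na in (5e-5, 2e-4, 1e-3):
        exp = make_dissociation_experiment(DEFAULT_STOCK, 100.0, na, scheme, rates)
        traces.append(
            generate_trace(
                exp, scheme, rates, NoiseModel(noise_sd, int(rng.integers(2**31)))
            )
        )
    return [_thin(t, points_per_trace) for t in traces]


@pytest.fixture(scope="session")
def clean_recovery_traces(asp_scheme, asp_rates):
    return make_recovery_traces(asp_scheme, asp_rates, 0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_recovery_traces(asp_scheme, asp_rates):
    return make_recovery_traces(asp_scheme, asp_rates, 0.02, seed=11)


@pytest.fixture(scope="session")
def perturbed_start(asp_rates):
    """Starting rate set with the free parameters displaced ~5-fold."""
    return asp_rates.updated(
        on3=asp_rates.on(3) * 5, off3=asp_rates.off(3) / 4, on4=asp_rates.on(4) / 6
    )


@pytest.fixture(scope="session")
def noisy_global_fit(noisy_recovery_traces, asp_scheme, perturbed_start):
    model = g.NetworkGlobalModel(noisy_recovery_traces, asp_scheme, perturbed_start)
    return model.fit(n_starts=3, seed=0)
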