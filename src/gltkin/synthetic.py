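"""Seeded synthetic relaxation datasets with the structure of the
published experiments.

No raw kinetic data are deposited for this system (the experiments exist
only as figures), so the package generates its own: noisy normalized
relaxation traces over the concentration grids of the binding,
dissociation and blocker experiments, with the dataset shapes of the
global fits (58 binding + 21 dissociation traces for the substrate
scheme, 68 blocker traces, 27 fast-mutant traces).  Datasets are pure
functions of (variant, seed, noise model, rate set): identical inputs
give bit-identical traces.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .scheme import KineticScheme, RateSet, build_scheme, canonical_rate_set
from .relaxation import (
    MixingExperiment,
    RelaxationTrace,
    make_binding_experiment,
    make_dissociation_experiment,
    simulate_experiment,
)

__all__ = [
    "NoiseModel",
    "DatasetManifest",
    "generate_trace",
    "generate_reference_dataset",
    "write_dataset",
    "read_dataset",
    "reference_grids",
]

#: default stock for dissociation experiments (M)
DEFAULT_STOCK = {"T": 25e-6, "Na": 10e-3, "A": 0.5e-3}


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian noise on the normalized signal.

    ``sd`` is the standard deviation as a fraction of the full signal
    amplitude (the normalized scale spans 0-1, so it is also the absolute
    sd).  The published traces show a few percent scatter; 2% is the
    default working level.
    """

    sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


def generate_trace(
    experiment: MixingExperiment,
    scheme: KineticScheme,
    rates: RateSet,
    noise: NoiseModel,
) -> RelaxationTrace:
    """Simulate one experiment and add seeded Gaussian noise.

    The metadata records the generating truth (variant, noise model, seed)
    so parameter-recovery studies can score against it.
    """
    trace = simulate_experiment(experiment, scheme, rates)
    rng = np.random.default_rng(noise.seed)
    signal = trace.signal + rng.normal(0.0, noise.sd, size=len(trace.signal))
    meta = dict(trace.metadata)
    meta.update({"noise_sd": noise.sd, "seed": noise.seed})
    return RelaxationTrace(trace.times, signal, meta)


@dataclass
class DatasetManifest:
    """Inventory of a generated dataset."""

    variant: str
    seed: int
    noise_sd: float
    entries: list = field(default_factory=list)  # {file, seed, experiment}
    rate_set: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        return cls(**d)


def reference_grids(variant: str) -> list[dict]:
    """Experiment designs reproducing the published dataset shapes.

    The publication lists ranges and trace counts but not the exact
    (Na+, ligand) pairing, so the grids here are declared choices:

    * substrate scheme: 58 binding traces = substrate
      {0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1, 2} mM x Na+
      {0.5, 1, 2, 3, 4, 6, 8} mM, plus {5, 10} mM substrate at 1 mM Na+;
      21 dissociation traces over final Na+ log-spaced 50 uM - 1 mM.
    * blocker scheme: 68 binding traces = 17 blocker concentrations
      (log-spaced 0.25 - 8 mM) x Na+ {4, 8, 12, 16} mM.
    * fast mutant: 27 binding traces = 9 substrate concentrations
      (0.025 - 10 mM) x Na+ {2, 4, 8} mM.
    """
    designs: list[dict] = []
    if variant in ("P11W_ASP", "FM_ASP"):
        if variant == "P11W_ASP":
            asp = [0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0]
            na = [0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
            extra = [(1.0, 5.0), (1.0, 10.0)]
        else:
            asp = [0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0]
            na = [2.0, 4.0, 8.0]
            extra = []
        for n in na:
            for a in asp:
                designs.append(
                    dict(direction="binding", na=n * 1e-3, ligand=a * 1e-3)
                )
        for n, a in extra:
            designs.append(dict(direction="binding", na=n * 1e-3, ligand=a * 1e-3))
        if variant == "P11W_ASP":
            for n in np.geomspace(50e-6, 1e-3, 21):
                designs.append(dict(direction="dissociation", na=float(n)))
    elif variant == "P11W_TBOA":
        for n in (4.0, 8.0, 12.0, 16.0):
            for b in np.geomspace(0.25, 8.0, 17):
                designs.append(
                    dict(direction="binding", na=n * 1e-3, ligand=float(b) * 1e-3)
                )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return designs


def generate_reference_dataset(
    variant: str,
    seed: int,
    noise_sd: float = 0.02,
    rates: RateSet | None = None,
    protein_total: float = 1e-6,
) -> tuple[DatasetManifest, list[RelaxationTrace]]:
    """Generate the full synthetic dataset for a variant.

    Per-trace seeds are drawn once from a generator seeded with ``seed``,
    so the dataset content is a pure function of
    (variant, seed, noise model, rate set).
    """
    scheme = build_scheme(variant)
    if rates is None:
        rates = canonical_rate_set(variant)
    designs = reference_grids(variant)
    rng = np.random.default_rng(seed)
    trace_seeds = rng.integers(0, 2**31 - 1, size=len(designs))
    manifest = DatasetManifest(variant, seed, noise_sd, [], rates.to_dict())
    traces = []
    for i, (design, s) in enumerate(zip(designs, trace_seeds)):
        if design["direction"] == "binding":
            exp = make_binding_experiment(
                protein_total, design["na"], design["ligand"], scheme, rates
            )
        else:
            exp = make_dissociation_experiment(
                DEFAULT_STOCK, 100.0, design["na"], scheme, rates
            )
        trace = generate_trace(exp, scheme, rates, NoiseModel(noise_sd, int(s)))
        fname = f"trace_{i:03d}_{design['direction']}.csv"
        manifest.entries.append(
            {"file": fname, "seed": int(s), "experiment": exp.to_dict()}
        )
        traces.append(trace)
    return manifest, traces


def write_dataset(manifest: DatasetManifest, traces, directory) -> None:
    """Write traces as CSV plus a manifest JSON into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    if len(traces) != len(manifest.entries):
        raise ValueError("trace count does not match manifest")
    for entry, trace in zip(manifest.entries, traces):
        trace.to_csv(os.path.join(directory, entry["file"]))
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)


def read_dataset(directory) -> tuple[DatasetManifest, list[RelaxationTrace]]:
    """Load a dataset directory; itemizes every missing or corrupt file."""
    mpath = os.path.join(directory, "manifest.json")
    if not os.path.exists(mpath):
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(mpath) as fh:
        manifest = DatasetManifest.from_dict(json.load(fh))
    problems = []
    traces = []
    for entry in manifest.entries:
        path = os.path.join(directory, entry["file"])
        if not os.path.exists(path):
            problems.append(f"missing trace file: {entry['file']}")
            continue
        try:
            traces.append(RelaxationTrace.from_csv(path))
        except Exception as exc:
            problems.append(f"unreadable trace file {entry['file']}: {exc}")
    if problems:
        raise FileNotFoundError("; ".join(problems))
    return manifest, traces
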