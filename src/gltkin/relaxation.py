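"""Experiment-shaped relaxation traces and observed-rate extraction.

Emulates the cuvette experiments: binding reactions start from apo
transporter equilibrated with Na+ before substrate addition; dissociation
reactions start from a pre-equilibrated concentrated stock diluted
100-fold into substrate-free buffer.  Signals are normalized bound
fractions (1 = fully bound plateau), sampled after a mixing dead time,
and observed rate constants come from single-exponential fits.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .scheme import (
    KineticScheme,
    RateSet,
    Trajectory,
    build_scheme,
    canonical_rate_set,
    equilibrium_state,
    simulate_timecourse,
)

__all__ = [
    "MixingExperiment",
    "RelaxationTrace",
    "ExpFitResult",
    "make_binding_experiment",
    "make_dissociation_experiment",
    "observable_from_trajectory",
    "fit_single_exponential",
    "kobs_surface",
    "simulate_experiment",
]

#: default mixing dead time (s) for manual cuvette addition with stirring
DEFAULT_DEAD_TIME = 2.0
#: default sampling interval (s); stretched for very slow relaxations so a
#: trace never exceeds ~600 points
DEFAULT_DT = 0.2
_MAX_POINTS = 600


@dataclass(frozen=True)
class MixingExperiment:
    """Post-mix composition and acquisition settings of one relaxation.

    For ``direction="binding"`` the transporter starts apo.  For
    ``direction="dissociation"`` the initial state is the pre-equilibrated
    stock composition divided by the dilution factor, with free ligands
    replaced by the dilution buffer (Na+ at ``na_total``, no substrate).
    """

    direction: str                 # "binding" | "dissociation"
    transporter_total: float       # M
    na_total: float                # M (free Na+ of the post-mix buffer)
    ligand_total: float            # M (total substrate/blocker carried)
    duration: float                # s
    dt: float                      # sampling interval, s
    dead_time: float = DEFAULT_DEAD_TIME
    stock: dict | None = None      # dissociation only: stock composition
    dilution_factor: float | None = None
    warnings_: tuple[str, ...] = ()

    def time_grid(self) -> np.ndarray:
        n = max(int(math.ceil(self.duration / self.dt)), 10)
        return np.linspace(self.duration / n, self.duration, n)

    def initial_state(self, scheme: KineticScheme, rates: RateSet) -> dict:
        if self.direction == "binding":
            return {
                "T": self.transporter_total,
                "Na": self.na_total,
                "A": self.ligand_total,
            }
        stock_eq = equilibrium_state(
            scheme,
            rates,
            {"T": self.stock["T"], "Na": self.stock["Na"], "A": self.stock["A"]},
        )
        d = self.dilution_factor
        init = {c: stock_eq.concentrations[c] / d for c in scheme.complexes}
        init["Na"] = self.na_total
        init["A"] = 0.0  # substrate-free dilution buffer
        return init

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warnings_"] = list(self.warnings_)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MixingExperiment":
        d = dict(d)
        d["warnings_"] = tuple(d.get("warnings_", ()))
        return cls(**d)


@dataclass
class RelaxationTrace:
    """A timestamped normalized-fluorescence record."""

    times: np.ndarray   # s, post-dead-time, strictly increasing
    signal: np.ndarray  # dimensionless, 1 = fully bound plateau
    metadata: dict = field(default_factory=dict)

    @property
    def experiment(self) -> MixingExperiment | None:
        exp = self.metadata.get("experiment")
        return MixingExperiment.from_dict(exp) if exp is not None else None

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.metadata, sort_keys=True) + "\n")
            fh.write("time_s,signal\n")
            for t, s in zip(self.times, self.signal):
                fh.write(f"{float(t)!r},{float(s)!r}\n")

    def plot(self, ax=None, **kwargs):
        """Quick-look plot of the trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.signal, ".", ms=3, **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized signal")
        return ax

    @classmethod
    def from_csv(cls, path) -> "RelaxationTrace":
        meta = {}
        with open(path) as fh:
            text = fh.read()
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                payload = line.lstrip("# ").strip()
                if payload:
                    meta.update(json.loads(payload))
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)), float_precision="round_trip")
        return cls(df["time_s"].to_numpy(), df["signal"].to_numpy(), meta)


@dataclass
class ExpFitResult:
    """Single-exponential fit of a relaxation trace."""

    k_obs: float
    amplitude: float
    offset: float
    rms: float
    converged: bool
    k_obs_stderr: float = float("nan")
    message: str = ""


def _pilot_kobs(
    scheme: KineticScheme, rates: RateSet, init: Mapping[str, float]
) -> float:
    """Coarse estimate of the relaxation rate from a log-grid pilot run."""
    grid = np.geomspace(1e-4, 3e5, 80)
    traj = simulate_timecourse(scheme, rates, init, grid, rtol=1e-6, atol=1e-14)
    sig = traj.bound_fraction()
    s0, s_inf = sig[0], sig[-1]
    amp = s_inf - s0
    if abs(amp) < 1e-9:
        return float("nan")
    frac = (sig - s0) / amp
    above = np.nonzero(frac >= 1.0 - 1.0 / math.e)[0]
    if len(above) == 0:
        return 1.0 / grid[-1]
    return 1.0 / grid[above[0]]


def make_binding_experiment(
    protein_total: float,
    na_total: float,
    ligand_total: float,
    scheme: KineticScheme | None = None,
    rates: RateSet | None = None,
    dead_time: float = DEFAULT_DEAD_TIME,
    dt: float = DEFAULT_DT,
    duration: float | None = None,
) -> MixingExperiment:
    """Design a binding relaxation (apo transporter + Na+ + ligand).

    The duration is auto-sized to ten relaxation times from a coarse pilot
    simulation (canonical rates unless given), so single-exponential fits
    always see the full amplitude.
    """
    if min(protein_total, na_total, ligand_total) < 0:
        raise ValueError("concentrations must be non-negative")
    if scheme is None:
        scheme = build_scheme("P11W_ASP")
    if rates is None:
        rates = canonical_rate_set(scheme.variant_id)
    if duration is None:
        if ligand_total == 0 or na_total == 0:
            duration = 60.0  # flat-signal design: no relaxation expected
        else:
            k = _pilot_kobs(
                scheme,
                rates,
                {"T": protein_total, "Na": na_total, "A": ligand_total},
            )
            duration = 60.0 if not np.isfinite(k) else 10.0 / k
    duration = max(duration, dead_time + 10 * dt)
    dt_eff = max(dt, duration / _MAX_POINTS)
    return MixingExperiment(
        direction="binding",
        transporter_total=protein_total,
        na_total=na_total,
        ligand_total=ligand_total,
        duration=float(duration),
        dt=float(dt_eff),
        dead_time=dead_time,
    )


def make_dissociation_experiment(
    stock: Mapping[str, float],
    dilution_factor: float,
    final_na: float,
    scheme: KineticScheme | None = None,
    rates: RateSet | None = None,
    dead_time: float = DEFAULT_DEAD_TIME,
    dt: float = DEFAULT_DT,
    duration: float | None = None,
) -> MixingExperiment:
    """Design a dilution-triggered dissociation relaxation.

    ``stock`` maps T/Na/A to the pre-equilibrated stock totals (M).  On
    dilution only protein-carried ligand survives: the free substrate is
    exchanged away by the substrate-free dilution buffer, and free Na+ is
    set by the buffer (``final_na``).  A warning is recorded if the stock
    is not ligand-saturated (< 90% bound).
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    if scheme is None:
        scheme = build_scheme("P11W_ASP")
    if rates is None:
        rates = canonical_rate_set(scheme.variant_id)
    stock = {k: float(stock.get(k, 0.0)) for k in ("T", "Na", "A")}
    stock_eq = equilibrium_state(scheme, rates, stock)
    warns = ()
    if stock_eq.bound_fraction < 0.90:
        warns = (
            f"stock only {stock_eq.bound_fraction:.1%} ligand-bound; "
            "dissociation amplitude will be reduced",
        )
        warnings.warn(warns[0])
    carried = sum(stock_eq.concentrations[c] for c in scheme.bound_complexes)
    exp = MixingExperiment(
        direction="dissociation",
        transporter_total=stock["T"] / dilution_factor,
        na_total=float(final_na),
        ligand_total=carried / dilution_factor,
        duration=1.0,  # placeholder, replaced below
        dt=dt,
        dead_time=dead_time,
        stock=stock,
        dilution_factor=float(dilution_factor),
        warnings_=warns,
    )
    if duration is None:
        k = _pilot_kobs(scheme, rates, exp.initial_state(scheme, rates))
        duration = 60.0 if not np.isfinite(k) else 10.0 / k
    duration = max(duration, dead_time + 10 * dt)
    dt_eff = max(dt, duration / _MAX_POINTS)
    return MixingExperiment(
        **{
            **exp.to_dict(),
            "duration": float(duration),
            "dt": float(dt_eff),
            "warnings_": warns,
        }
    )


def observable_from_trajectory(
    trajectory: Trajectory,
    dead_time: float = DEFAULT_DEAD_TIME,
    weights: Mapping[str, float] | None = None,
    metadata: dict | None = None,
) -> RelaxationTrace:
    """Noise-free normalized signal from a simulated trajectory.

    The signal is the (optionally weighted) sum of substrate-bound complex
    concentrations over total transporter; all bound complexes contribute
    equally by default (intermediates are negligibly populated so the
    weighting is inconsequential, but it is explicit and configurable).
    Points within the dead time are discarded.
    """
    keep = trajectory.times >= dead_time
    sig = trajectory.bound_fraction(weights)[keep]
    return RelaxationTrace(
        trajectory.times[keep], sig, dict(metadata or {})
    )


def simulate_experiment(
    experiment: MixingExperiment,
    scheme: KineticScheme,
    rates: RateSet,
    weights: Mapping[str, float] | None = None,
    rtol: float = 1e-8,
) -> RelaxationTrace:
    """Simulate one experiment and return its noise-free trace."""
    traj = simulate_timecourse(
        scheme, rates, experiment.initial_state(scheme, rates),
        experiment.time_grid(), rtol=rtol,
    )
    meta = {"experiment": experiment.to_dict(), "variant": scheme.variant_id}
    return observable_from_trajectory(
        traj, dead_time=experiment.dead_time, weights=weights, metadata=meta
    )


def fit_single_exponential(trace: RelaxationTrace) -> ExpFitResult:
    """Least-squares fit of offset + amplitude * exp(-k_obs t).

    The amplitude sign is unconstrained, handling rising and decaying
    traces identically.  Initial guesses: endpoints for offset/amplitude,
    the half-amplitude crossing time for k_obs.  A flat trace or a rate
    pinned at the parameter bounds is flagged as a failure, never reported
    silently.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.signal, dtype=float)
    if len(t) < 10:
        return ExpFitResult(
            float("nan"), 0.0, float(np.mean(y)) if len(y) else 0.0,
            float("nan"), False, message="fewer than 10 points",
        )
    t0 = t[0]
    y0, y_inf = float(y[0]), float(np.mean(y[-max(3, len(y) // 20):]))
    amp0 = y0 - y_inf
    span = float(np.ptp(y))
    if span < 1e-6 or abs(amp0) < 0.02 * span:
        # essentially constant, or endpoints indistinguishable from noise
        amp0 = span if y[0] > y[-1] else -span
    if span < 1e-6:
        return ExpFitResult(
            float("nan"), 0.0, y_inf, float(np.std(y)), False,
            message="no relaxation (constant trace)",
        )
    # half-amplitude crossing for the rate guess
    frac = (y - y_inf) / amp0 if amp0 != 0 else np.zeros_like(y)
    below = np.nonzero(frac <= 0.5)[0]
    if len(below) and below[0] > 0:
        k0 = math.log(2.0) / max(t[below[0]] - t0, t[1] - t[0])
    else:
        k0 = 1.0 / max(t[-1] - t0, 1e-9)
    k_lo, k_hi = 1e-9, 1e6

    def resid(p):
        k, a, c = p
        return c + a * np.exp(-k * (t - t0)) - y

    res = least_squares(
        resid,
        x0=[k0, amp0, y_inf],
        bounds=([k_lo, -np.inf, -np.inf], [k_hi, np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    k, a, c = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    at_bound = bool(k <= k_lo * 1.01 or k >= k_hi * 0.99)
    converged = bool(res.success and not at_bound and abs(a) > 1e-6)
    # rescale amplitude/offset to absolute t=0 (a already refers to t0)
    stderr = float("nan")
    if converged and res.jac is not None:
        try:
            dof = max(len(t) - 3, 1)
            cov = np.linalg.inv(res.jac.T @ res.jac) * (2 * res.cost / dof)
            stderr = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            pass
    msg = "" if converged else ("k_obs at bound" if at_bound else res.message)
    return ExpFitResult(float(k), float(a), float(c), rms, converged, stderr, msg)


def kobs_surface(
    scheme: KineticScheme,
    rates: RateSet,
    na_list,
    ligand_list,
    direction: str = "binding",
    protein_total: float = 1e-6,
    stock: Mapping[str, float] | None = None,
    dilution_factor: float = 100.0,
    **exp_kwargs,
) -> pd.DataFrame:
    """Observed-rate table over a (Na+, ligand) grid.

    One simulate -> observe -> fit pass per grid point; per-cell failures
    are recorded in the ``converged`` column rather than raised.  For
    ``direction="dissociation"`` the grid is over final Na+ only (the
    carried ligand is set by the stock; ``ligand_list`` is ignored).
    """
    if len(list(na_list)) == 0:
        raise ValueError("na_list must be non-empty")
    rows = []
    if direction == "dissociation":
        if stock is None:
            stock = {"T": 25e-6, "Na": 10e-3, "A": 0.5e-3}
        for na in na_list:
            exp = make_dissociation_experiment(
                stock, dilution_factor, na, scheme, rates, **exp_kwargs
            )
            fit = fit_single_exponential(simulate_experiment(exp, scheme, rates))
            rows.append(
                dict(na=na, ligand=exp.ligand_total, k_obs=fit.k_obs,
                     converged=fit.converged, rms=fit.rms)
            )
    else:
        if len(list(ligand_list)) == 0:
            raise ValueError("ligand_list must be non-empty")
        for na in na_list:
            for lig in ligand_list:
                exp = make_binding_experiment(
                    protein_total, na, lig, scheme, rates, **exp_kwargs
                )
                fit = fit_single_exponential(
                    simulate_experiment(exp, scheme, rates)
                )
                rows.append(
                    dict(na=na, ligand=lig, k_obs=fit.k_obs,
                         converged=fit.converged, rms=fit.rms)
                )
    return pd.DataFrame(rows)
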