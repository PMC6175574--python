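"""Fitting stages: Hill-gated dissociation, conformational selection, and
constrained global fitting of the full network.

Each stage is a Model object built from data whose ``fit()`` returns a
Results object carrying the estimates, their standard errors, diagnostics
and a ``summary()`` table:

* :class:`HillDissociationModel` -- k_obs,d versus [Na+], fitted to the
  locking-ion gating law with the Hill coefficient fixed (default grid
  n in {1, 2, 3}).
* :class:`ConformationalSelectionModel` -- k_obs versus ligand at several
  Na+ concentrations, fitted jointly with the reverse-isomerization rate
  shared across Na+ datasets (rapid-equilibrium form for the blocker,
  full two-step form for the substrate with externally supplied k_off).
* :class:`NetworkGlobalModel` -- raw relaxation traces fitted by
  simulating the full mass-action network at trial rate constants, with
  the Na+ parameters fixed and the thermodynamic cycle enforced by
  construction (off4 is computed from on4, K_D3, K_D5, K_D2, so the free
  parameters of the substrate scheme are exactly {on3, off3, on4}).

Optimization of the network model runs in log-parameter space with seeded
multi-start; the objective is the unweighted sum of squared residuals on
the normalized traces, and chi-square values are reported in those units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import lmfit
from scipy.optimize import least_squares

from . import closed_forms as cf
from .scheme import (
    KineticScheme,
    RateSet,
    check_detailed_balance,
    simulate_timecourse,
)
from .relaxation import MixingExperiment, RelaxationTrace

__all__ = [
    "HillDissociationModel",
    "HillFitResult",
    "ConformationalSelectionModel",
    "CSFitResult",
    "NetworkGlobalModel",
    "GlobalFitResult",
    "ModelComparisonResult",
    "fit_hill_dissociation",
    "fit_cs",
    "fit_line_origin",
    "global_fit_network",
    "branch_exclusion_test",
    "BRANCHES",
]


def _stderr(params: lmfit.Parameters, name: str) -> float:
    se = params[name].stderr
    return float(se) if se is not None else float("nan")


# ---------------------------------------------------------------------------
# Hill-gated dissociation (locking-ion release)
# ---------------------------------------------------------------------------

@dataclass
class HillFitResult:
    """Fitted Na+-gated dissociation parameters."""

    params: cf.HillDissociationParams
    stderr: dict[str, float]
    rss: float
    n_used: float
    converged: bool
    flags: tuple[str, ...] = ()

    def summary(self) -> str:
        p, se = self.params, self.stderr
        lines = [
            "Na+-gated dissociation fit (k_obs,d = k_off,asp K^n/([Na]^n + K^n))",
            f"  Hill n (fixed)   : {self.n_used:g}",
            f"  k_off,asp (s^-1) : {p.k_off_asp:.4g} +/- {se['k_off_asp']:.2g}",
            f"  K_D,Na (M)       : {p.kd_na:.4g} +/- {se['kd_na']:.2g}",
            f"  RSS              : {self.rss:.4g}",
        ]
        if self.flags:
            lines.append("  flags            : " + "; ".join(self.flags))
        return "\n".join(lines)


class HillDissociationModel:
    """Model for dissociation rate constants versus Na+ concentration."""

    def __init__(self, na, kobs_d, weights=None):
        self.na = np.asarray(na, dtype=float)
        self.kobs = np.asarray(kobs_d, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, float)
        if len(self.na) < 4:
            raise ValueError("need at least 4 (na, k_obs,d) points")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, na_col="na", kobs_col="k_obs"):
        return cls(df[na_col].to_numpy(), df[kobs_col].to_numpy())

    def fit(self, n: float = 2.0) -> HillFitResult:
        if not 0.5 <= n <= 4:
            raise ValueError("Hill coefficient restricted to [0.5, 4]")
        flags: list[str] = []
        rel_span = np.ptp(self.kobs) / max(np.mean(self.kobs), 1e-300)
        pars = lmfit.Parameters()
        pars.add("k_off_asp", value=float(np.max(self.kobs)), min=1e-12)
        # half-point guess: Na where kobs crosses half its maximum
        half = np.max(self.kobs) / 2
        below = np.nonzero(self.kobs <= half)[0]
        kd0 = self.na[below[0]] if len(below) else float(np.median(self.na))
        pars.add("kd_na", value=max(kd0, 1e-9), min=1e-12)

        def resid(p):
            model = cf.kobs_dissociation_hill(
                cf.HillDissociationParams(p["k_off_asp"].value, p["kd_na"].value, n),
                self.na,
            )
            r = model - self.kobs
            return r if self.weights is None else r * self.weights

        out = lmfit.minimize(resid, pars, method="leastsq")
        p = out.params
        result = cf.HillDissociationParams(
            float(p["k_off_asp"].value), float(p["kd_na"].value), n
        )
        se = {k: _stderr(p, k) for k in ("k_off_asp", "kd_na")}
        if rel_span < 0.05:
            flags.append("kd_na unidentifiable: k_obs,d shows no Na+ dependence")
        for k in ("k_off_asp", "kd_na"):
            if not np.isfinite(se[k]) or se[k] > abs(p[k].value):
                flags.append(f"{k} poorly determined (relative SE > 100%)")
        return HillFitResult(
            result, se, float(np.sum(np.asarray(out.residual) ** 2)), n,
            bool(out.success), tuple(flags),
        )


def fit_hill_dissociation(kobs_table, n_fixed: float = 2.0) -> HillFitResult:
    """Fit the gating law to a table of (na, k_obs) with fixed Hill n."""
    if isinstance(kobs_table, pd.DataFrame):
        model = HillDissociationModel.from_dataframe(kobs_table)
    else:
        na, k = kobs_table
        model = HillDissociationModel(na, k)
    return model.fit(n=n_fixed)


# ---------------------------------------------------------------------------
# Conformational selection (shared reverse-isomerization rate)
# ---------------------------------------------------------------------------

@dataclass
class CSFitResult:
    """Per-Na+ forward isomerization rates with shared reverse rate."""

    mode: str
    k_r: dict[float, float]
    k_r_stderr: dict[float, float]
    k_minus_r: float
    k_minus_r_stderr: float
    per_na: dict[str, dict[float, float]]  # kd_ligand (rapid_eq) or k_on (full)
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()

    def slope_through_origin(self):
        """Slope of k_r versus Na+ constrained through the origin."""
        na = np.array(sorted(self.k_r))
        kr = np.array([self.k_r[x] for x in na])
        return fit_line_origin(na, kr)

    def summary(self) -> str:
        lines = [f"conformational-selection fit (mode={self.mode})"]
        for na in sorted(self.k_r):
            lines.append(
                f"  k_r @ Na={na * 1e3:g} mM : {self.k_r[na]:.4g}"
                f" +/- {self.k_r_stderr[na]:.2g} s^-1"
            )
        lines.append(
            f"  shared k_-r : {self.k_minus_r:.4g}"
            f" +/- {self.k_minus_r_stderr:.2g} s^-1"
        )
        for name, by_na in self.per_na.items():
            for na in sorted(by_na):
                lines.append(f"  {name} @ Na={na * 1e3:g} mM : {by_na[na]:.4g}")
        if self.flags:
            lines.append("  flags : " + "; ".join(self.flags))
        slope, se = self.slope_through_origin()
        lines.append(f"  k_r vs Na+ slope (origin) : {slope:.4g} +/- {se:.2g} M^-1 s^-1")
        return "\n".join(lines)


class ConformationalSelectionModel:
    """Joint fit of k_obs-versus-ligand curves at several Na+ concentrations.

    ``data_by_na`` maps Na+ concentration (M) to ``(ligand, k_obs)`` arrays.
    Only the reverse isomerization rate k_-r is shared across datasets (it
    is Na+-independent); the ligand-capture parameter (K_D for
    ``mode="rapid_eq"``, k_on for ``mode="full"``) is per dataset, since
    the effective capture rate carries its own Na+ dependence through the
    branch split.  ``mode="full"`` additionally needs k_off per Na+
    supplied externally (conventionally from the dissociation-rate fit).
    """

    def __init__(
        self,
        data_by_na: Mapping[float, tuple],
        mode: str = "full",
        koff_by_na: Mapping[float, float] | None = None,
    ):
        if mode not in ("full", "rapid_eq"):
            raise ValueError("mode must be 'full' or 'rapid_eq'")
        if len(data_by_na) < 2:
            raise ValueError("shared-parameter fitting needs >= 2 Na+ datasets")
        self.mode = mode
        self.data = {
            float(na): (np.asarray(L, float), np.asarray(k, float))
            for na, (L, k) in data_by_na.items()
        }
        for na, (L, k) in self.data.items():
            if len(L) < 4:
                raise ValueError(f"dataset at Na={na} has fewer than 4 points")
        if mode == "full":
            if koff_by_na is None:
                raise ValueError("mode='full' requires externally supplied k_off")
            self.koff = {float(na): float(koff_by_na[na]) for na in data_by_na}

    def _make_params(self, na_keys, kr_guess: str) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        for i, na in enumerate(na_keys):
            _, k = self.data[na]
            guess = float(np.max(k)) if kr_guess == "max" else float(np.min(k))
            pars.add(
                f"log_kr_{i}", value=math.log10(max(guess, 1e-9)), min=-9, max=6
            )
        kmax = max(float(np.max(k)) for _, k in self.data.values())
        pars.add("log_kmr", value=math.log10(10 * kmax), min=-6, max=8)
        for i, na in enumerate(na_keys):
            L, k = self.data[na]
            Lmed = float(np.median(L))
            if self.mode == "rapid_eq":
                pars.add(f"log_kd_{i}", value=math.log10(Lmed), min=-9, max=2)
            else:
                pars.add(
                    f"log_kon_{i}",
                    value=math.log10(max(float(np.max(k)) / Lmed, 1e-9)),
                    min=-3, max=12,
                )
        return pars

    def fit(self) -> CSFitResult:
        na_keys = sorted(self.data)

        def resid(p):
            out = []
            for i, na in enumerate(na_keys):
                L, k = self.data[na]
                kr = 10.0 ** p[f"log_kr_{i}"].value
                kmr = 10.0 ** p["log_kmr"].value
                if self.mode == "rapid_eq":
                    model = cf.kobs_cs_rapid_eq(
                        cf.CSParams(
                            kr, kmr, kd_ligand=10.0 ** p[f"log_kd_{i}"].value
                        ),
                        L,
                    )
                else:
                    model = cf.kobs_cs_full(
                        cf.CSParams(
                            kr, kmr,
                            k_on=10.0 ** p[f"log_kon_{i}"].value,
                            k_off=self.koff[na],
                        ),
                        L,
                    )
                out.append(model - k)
            return np.concatenate(out)

        # two deterministic starts (plateau near the data max or min) guard
        # against the local minimum where a k_r collapses to zero
        fit = None
        for guess in ("max", "min"):
            cand = lmfit.minimize(
                resid, self._make_params(na_keys, guess),
                method="leastsq", max_nfev=20000,
            )
            if fit is None or float(np.sum(np.asarray(cand.residual) ** 2)) < float(
                np.sum(np.asarray(fit.residual) ** 2)
            ):
                fit = cand
        p = fit.params
        ln10 = math.log(10.0)
        k_r, k_r_se = {}, {}
        for i, na in enumerate(na_keys):
            val = 10.0 ** p[f"log_kr_{i}"].value
            se_log = _stderr(p, f"log_kr_{i}")
            k_r[na] = float(val)
            k_r_se[na] = float(val * ln10 * se_log)
        kmr = 10.0 ** p["log_kmr"].value
        kmr_se = kmr * ln10 * _stderr(p, "log_kmr")
        base = "log_kd" if self.mode == "rapid_eq" else "log_kon"
        key = "kd_ligand" if self.mode == "rapid_eq" else "k_on"
        per_na = {
            key: {
                na: float(10.0 ** p[f"{base}_{i}"].value)
                for i, na in enumerate(na_keys)
            }
        }
        flags: list[str] = []
        correlated = not np.isfinite(kmr_se)
        if p["log_kmr"].correl:
            for i in range(len(na_keys)):
                c = p["log_kmr"].correl.get(f"{base}_{i}")
                if c is not None and abs(c) > 0.95:
                    correlated = True
        if correlated:
            flags.append(
                f"k_-r and {key} are correlated and not independently determined"
            )
        return CSFitResult(
            self.mode, k_r, k_r_se, float(kmr), float(kmr_se), per_na,
            float(np.sum(np.asarray(fit.residual) ** 2)),
            bool(fit.success), tuple(flags),
        )


def fit_cs(kobs_tables_by_na, mode="full", koff_by_na=None) -> CSFitResult:
    """Functional wrapper around :class:`ConformationalSelectionModel`."""
    return ConformationalSelectionModel(kobs_tables_by_na, mode, koff_by_na).fit()


def fit_line_origin(x, y) -> tuple[float, float]:
    """Least-squares slope of y = s*x constrained through the origin.

    Returns ``(slope, stderr)``; the standard error uses the residual
    variance with n-1 degrees of freedom (nan for a single point).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1:
        raise ValueError("need at least one point")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all x values are zero; slope undefined")
    slope = float(np.sum(x * y) / sxx)
    if len(x) < 2:
        return slope, float("nan")
    resid = y - slope * x
    se = math.sqrt(float(np.sum(resid**2)) / (len(x) - 1) / sxx)
    return slope, se


# ---------------------------------------------------------------------------
# Constrained global fit of the full network
# ---------------------------------------------------------------------------

#: branch name -> reaction whose rates are disabled when the branch is excluded
BRANCHES = {"asp_binds_first": 3, "second_na_binds_first": 4}


@dataclass
class GlobalFitResult:
    """Fitted rate set with chi-square accounting and identifiability flags."""

    rates: RateSet
    params: dict[str, float]
    stderr: dict[str, float]
    chi2: float
    per_trace_chi2: np.ndarray
    fixed_mask: tuple[str, ...]
    converged: bool
    flags: tuple[str, ...] = ()
    n_starts: int = 1
    start_chi2: tuple[float, ...] = ()

    def summary(self) -> str:
        lines = [
            "global network fit (cycle-constrained; normalized-signal units)",
            f"  chi^2 total : {self.chi2:.6g}  over {len(self.per_trace_chi2)} traces",
            f"  converged   : {self.converged}  (best of {self.n_starts} starts)",
        ]
        for k in self.params:
            lines.append(
                f"  {k:>5s} : {self.params[k]:.5g} +/- {self.stderr[k]:.2g}"
            )
        res = check_detailed_balance(self.rates)
        lines.append(f"  cycle residual : {res:.2e}")
        if self.flags:
            lines.append("  flags : " + "; ".join(self.flags))
        return "\n".join(lines)


@dataclass
class ModelComparisonResult:
    """Nested-model chi-square comparison for branch exclusion."""

    chi2_full: float
    chi2_excluded: float
    branch: str | None
    excluded_fit: GlobalFitResult | None = None

    @property
    def percent_increase(self) -> float:
        return 100.0 * (self.chi2_excluded - self.chi2_full) / self.chi2_full


class NetworkGlobalModel:
    """Global fit of relaxation traces by full network simulation.

    Every trace must carry its experiment record in ``metadata``.  The model
    signal for a trial rate set is obtained by rebuilding the experiment's
    initial state (apo mix for binding; re-equilibrated, diluted stock for
    dissociation), integrating the mass-action ODEs on the trace's time
    grid, and taking the bound fraction.  The Na+ parameters are fixed and
    the thermodynamic cycle is enforced by construction, leaving
    {on3, off3, on4} free for the substrate scheme (off4 follows from the
    cycle).  When a branch is excluded its committing reaction is disabled
    kinetically while the equilibrium weights are preserved through the
    cycle, and the surviving ligand reaction's on/off rates are both free.
    """

    def __init__(
        self,
        traces: Sequence[RelaxationTrace],
        scheme: KineticScheme,
        start_rates: RateSet,
        exclude_branch: str | None = None,
        sim_rtol: float = 1e-7,
    ):
        if not traces:
            raise ValueError("no traces supplied")
        self.traces = list(traces)
        self.scheme = scheme
        self.start = start_rates
        self.sim_rtol = sim_rtol
        if exclude_branch is not None and exclude_branch not in BRANCHES:
            raise ValueError(f"branch must be one of {sorted(BRANCHES)} or None")
        self.exclude_branch = exclude_branch
        if exclude_branch is None:
            self.free_names = ("on3", "off3", "on4")
        elif exclude_branch == "asp_binds_first":
            self.free_names = ("on4", "off4")
        else:
            self.free_names = ("on3", "off3")
        self._experiments = []
        for tr in self.traces:
            exp = tr.experiment
            if exp is None:
                raise ValueError("every trace needs an experiment record")
            self._experiments.append(exp)

    # -- parameter mapping -------------------------------------------------
    def rates_from_theta(self, theta: np.ndarray) -> RateSet:
        vals = {n: 10.0 ** t for n, t in zip(self.free_names, theta)}
        rs = self.start
        if self.exclude_branch is None:
            on3, off3, on4 = vals["on3"], vals["off3"], vals["on4"]
            off4 = on4 * (off3 / on3) * rs.kd(5) / rs.kd(2)  # cycle closure
            return rs.updated(on3=on3, off3=off3, on4=on4, off4=off4)
        if self.exclude_branch == "asp_binds_first":
            # disable reaction 3 kinetically, keep its equilibrium weight
            # consistent with the cycle so stock equilibration is unchanged
            on4, off4 = vals["on4"], vals["off4"]
            kd3 = rs.kd(2) * (off4 / on4) / rs.kd(5)
            eps = 1e-30
            return rs.updated(on3=eps, off3=eps * kd3, on4=on4, off4=off4)
        on3, off3 = vals["on3"], vals["off3"]
        kd4 = (off3 / on3) * rs.kd(5) / rs.kd(2)
        eps = 1e-30
        return rs.updated(on3=on3, off3=off3, on4=eps, off4=eps * kd4)

    def theta_start(self) -> np.ndarray:
        return np.array(
            [
                math.log10(
                    self.start.on(int(n[-1])) if n.startswith("on")
                    else self.start.off(int(n[-1]))
                )
                for n in self.free_names
            ]
        )

    # -- objective ---------------------------------------------------------
    def _trace_model(self, rates: RateSet, i: int) -> np.ndarray:
        exp = self._experiments[i]
        tr = self.traces[i]
        traj = simulate_timecourse(
            self.scheme, rates, exp.initial_state(self.scheme, rates),
            tr.times, rtol=self.sim_rtol, atol=1e-14,
        )
        return traj.bound_fraction()

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        rates = self.rates_from_theta(theta)
        out = []
        for i, tr in enumerate(self.traces):
            try:
                model = self._trace_model(rates, i)
            except Exception:
                model = np.full_like(tr.signal, 1e3)  # penalize failed trials
            out.append(model - tr.signal)
        return np.concatenate(out)

    def chi2(self, rates: RateSet) -> tuple[float, np.ndarray]:
        per = np.empty(len(self.traces))
        for i, tr in enumerate(self.traces):
            r = self._trace_model(rates, i) - tr.signal
            per[i] = float(np.sum(r * r))
        return float(per.sum()), per

    # -- fit ---------------------------------------------------------------
    def fit(
        self,
        n_starts: int = 5,
        seed: int = 0,
        spread: float = 0.5,
        xtol: float = 1e-10,
    ) -> GlobalFitResult:
        """Multi-start least squares in log10 parameter space.

        The first start is the supplied rate set; the remaining starts
        perturb each free log10 parameter uniformly within ``+/- spread``
        decades (seeded).
        """
        rng = np.random.default_rng(seed)
        theta0 = self.theta_start()
        starts = [theta0]
        for _ in range(n_starts - 1):
            starts.append(theta0 + rng.uniform(-spread, spread, len(theta0)))
        best = None
        start_chi2 = []
        for s in starts:
            res = least_squares(
                self.residuals, s, method="trf", xtol=xtol, ftol=1e-12, gtol=1e-12,
                diff_step=1e-5,
            )
            start_chi2.append(2 * res.cost)
            if best is None or res.cost < best.cost:
                best = res
        theta = best.x
        rates = self.rates_from_theta(theta)
        chi2, per = self.chi2(rates)
        # standard errors from the Jacobian at the optimum (log10 space)
        n_pts = sum(len(t.times) for t in self.traces)
        dof = max(n_pts - len(theta), 1)
        flags: list[str] = []
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * (chi2 / dof)
            se_log = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se_log = np.full(len(theta), np.nan)
            flags.append("singular Jacobian: covariance unavailable")
        ln10 = math.log(10.0)
        params, stderr = {}, {}
        for name, t, sl in zip(self.free_names, theta, se_log):
            val = 10.0**t
            params[name] = float(val)
            stderr[name] = float(val * ln10 * sl)
            if not np.isfinite(sl) or val * ln10 * sl > val:
                flags.append(f"{name}: lower limit only (relative SE > 100%)")
        fixed = tuple(
            f"{kind}{i}"
            for i in sorted(r.index for r in self.scheme.reactions)
            for kind in ("on", "off")
            if f"{kind}{i}" not in self.free_names and not (
                self.exclude_branch is not None
                and i == BRANCHES[self.exclude_branch]
            )
        )
        return GlobalFitResult(
            rates, params, stderr, chi2, per, fixed,
            bool(best.success), tuple(flags), len(starts), tuple(start_chi2),
        )


def global_fit_network(
    traces,
    scheme: KineticScheme,
    initial_rates: RateSet,
    n_starts: int = 5,
    seed: int = 0,
    **kwargs,
) -> GlobalFitResult:
    """Fit {on3, off3, on4} of the network to a trace collection."""
    model = NetworkGlobalModel(traces, scheme, initial_rates, **kwargs)
    return model.fit(n_starts=n_starts, seed=seed)


def branch_exclusion_test(
    traces,
    scheme: KineticScheme,
    rates: RateSet,
    branch: str | None,
    n_starts: int = 3,
    seed: int = 0,
) -> ModelComparisonResult:
    """Chi-square comparison after removing one assembly branch.

    ``rates`` is taken as the already-fitted full model; the reduced model
    (the committing reaction of ``branch`` disabled) is refitted from the
    same starting values.  ``branch=None`` performs no exclusion and
    returns a zero increase.
    """
    base = NetworkGlobalModel(traces, scheme, rates)
    chi2_full, _ = base.chi2(rates)
    if branch is None:
        return ModelComparisonResult(chi2_full, chi2_full, None)
    excl_model = NetworkGlobalModel(traces, scheme, rates, exclude_branch=branch)
    excl_fit = excl_model.fit(n_starts=n_starts, seed=seed)
    return ModelComparisonResult(chi2_full, excl_fit.chi2, branch, excl_fit)
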