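"""Closed-form observed-rate and branch-flux expressions.

These are the analytical models used to interpret single-exponential
relaxation rate constants:

* a naive fully-concerted law (k_obs = k_off + k_on [Na]^3 [A]) kept as the
  rejected reference model,
* a Hill-gated dissociation law in which the substrate can only leave once
  the rapidly equilibrating "locking" Na+ ions have dissociated,
* the conformational-selection relaxation rate in its rapid-equilibrium and
  full two-step forms, and
* the rapid-equilibrium branch fractions and flux ratios of the two
  alternative assembly paths ("second Na+ binds first" through TNa2 versus
  "substrate binds first" through TANa).

All functions are pure and vectorize over their concentration arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillDissociationParams",
    "CSParams",
    "BranchFractions",
    "kobs_naive_cubic",
    "kobs_dissociation_hill",
    "kobs_cs_rapid_eq",
    "kobs_cs_full",
    "branch_fractions",
    "binding_flux_ratio",
    "dissociation_flux_ratio",
    "crossover_na",
]


@dataclass(frozen=True)
class HillDissociationParams:
    """Parameters of the Na+-gated dissociation law.

    k_off_asp : intrinsic substrate off-rate once the locking ions are
        released (s^-1).
    kd_na : half-saturation concentration of the locking ions (M).
    n : Hill coefficient (the experiments are fitted with n in {1, 2, 3};
        non-integer n is permitted, bounded to [0.5, 4] for fitting).
    """

    k_off_asp: float
    kd_na: float
    n: float = 2.0

    def __post_init__(self):
        if min(self.k_off_asp, self.kd_na, self.n) <= 0:
            raise ValueError("all parameters must be positive")


@dataclass(frozen=True)
class CSParams:
    """Parameters of the Na+-driven conformational-selection scheme.

    k_r : forward isomerization rate into the binding-competent state
        (s^-1); carries the Na+ dependence.
    k_minus_r : reverse isomerization rate (s^-1).
    kd_ligand : ligand affinity for the binding-competent state (M); used
        by the rapid-equilibrium form.
    k_on, k_off : ligand binding/unbinding rate constants of the full
        two-step form (M^-1 s^-1, s^-1).
    """

    k_r: float
    k_minus_r: float
    kd_ligand: float | None = None
    k_on: float | None = None
    k_off: float | None = None


@dataclass(frozen=True)
class BranchFractions:
    """Rapid-equilibrium occupancies of the TNa2/TNa branch points."""

    f_tna2: float
    f_tna: float


def kobs_naive_cubic(k_on: float, k_off: float, na, asp):
    """Fully concerted law: k_obs = k_off + k_on [Na]^3 [A].

    ``k_on`` is the composite fourth-order constant (M^-4 s^-1).  The data
    reject this law (observed Na+ dependence is quadratic-to-linear, not
    cubic); it is provided as the reference model.
    """
    na = np.asarray(na, dtype=float)
    asp = np.asarray(asp, dtype=float)
    return k_off + k_on * na**3 * asp


def kobs_dissociation_hill(params: HillDissociationParams, na):
    """Observed dissociation rate gated by locking-ion occupancy.

    k_obs,d = k_off,asp * K_D,Na^n / ([Na]^n + K_D,Na^n): the substrate
    leaves at its intrinsic rate times the fraction of complexes whose
    rapidly equilibrating ions are off.  Strictly decreasing in [Na].
    """
    na = np.asarray(na, dtype=float)
    kn = params.kd_na**params.n
    return params.k_off_asp * kn / (na**params.n + kn)


def kobs_cs_rapid_eq(params: CSParams, ligand):
    """Conformational-selection rate under the rapid-equilibrium limit.

    k_obs = k_r + k_-r * K_D / (K_D + [L]); valid when ligand binding and
    unbinding are fast relative to the isomerization.  Decreases with
    ligand concentration toward the plateau k_r.
    """
    if params.kd_ligand is None:
        raise ValueError("kd_ligand is required for the rapid-equilibrium form")
    ligand = np.asarray(ligand, dtype=float)
    return params.k_r + params.k_minus_r * params.kd_ligand / (
        params.kd_ligand + ligand
    )


def kobs_cs_full(params: CSParams, ligand):
    """Slow relaxation rate of the full two-step selection scheme.

    The smaller-magnitude nonzero eigenvalue of the linear system
    T* <-> T <-> TL (isomerization k_r/k_-r followed by binding
    k_on[L]/k_off)::

        k_obs = (k_-r + k_r + k_off + k_on L
                 - sqrt((k_off + k_on L - k_-r - k_r)^2 + 4 k_-r k_on L)) / 2

    The radical form cancels catastrophically when k_on*L dominates every
    first-order rate, so the algebraically identical stable root
    k_obs = 2P / (S + sqrt(S^2 - 4P)) is evaluated instead, with
    S = k_r + k_-r + k_off + k_on L (eigenvalue sum) and
    P = k_r (k_on L + k_off) + k_-r k_off (eigenvalue product); the
    discriminant S^2 - 4P equals the radical argument above and is
    computed in that positive form.  The plateau at L -> inf is exactly
    k_r.
    """
    if params.k_on is None or params.k_off is None:
        raise ValueError("k_on and k_off are required for the full form")
    kr, kmr, kon, koff = params.k_r, params.k_minus_r, params.k_on, params.k_off
    L = np.asarray(ligand, dtype=float)
    konL = kon * L
    S = kr + kmr + koff + konL
    P = kr * (konL + koff) + kmr * koff
    delta = konL + koff - kmr - kr
    disc = delta * delta + 4.0 * kmr * konL  # = S^2 - 4P, cancellation-free
    return 2.0 * P / (S + np.sqrt(disc))


def branch_fractions(na: float, kd2: float) -> BranchFractions:
    """Rapid-equilibrium split of the ion-only pool between TNa2 and TNa.

    F_TNa2 = [Na]/(K_D2+[Na]); F_TNa = K_D2/(K_D2+[Na]).  These weight the
    two substrate-committing steps during assembly.
    """
    if na < 0 or kd2 <= 0:
        raise ValueError("na must be >= 0 and kd2 > 0")
    f2 = na / (kd2 + na)
    return BranchFractions(f_tna2=f2, f_tna=1.0 - f2)


def binding_flux_ratio(na, kd2: float, on4: float, on3: float):
    """Assembly flux ratio (TNa2 path over TANa path).

    eta_TNa2/eta_TANa = ([Na]/K_D2) * (k_on4/k_on3); exactly linear in [Na].
    """
    if kd2 <= 0 or on4 < 0 or on3 <= 0:
        raise ValueError("rate constants must be positive (on4 >= 0)")
    na = np.asarray(na, dtype=float)
    return (na / kd2) * (on4 / on3)


def dissociation_flux_ratio(na, kd5: float, off4: float, off3: float):
    """Disassembly flux ratio (TNa2 path over TANa path).

    rho_TNa2/rho_TANa = ([Na]/K_D5) * (k_off4/k_off3); linear in [Na].
    """
    if kd5 <= 0 or off4 < 0 or off3 <= 0:
        raise ValueError("rate constants must be positive (off4 >= 0)")
    na = np.asarray(na, dtype=float)
    return (na / kd5) * (off4 / off3)


def crossover_na(kd: float, rate_ratio: float) -> float:
    """Na+ concentration (M) at which a branch-flux ratio equals one.

    For a ratio ([Na]/K_D) * r the crossover is K_D / r.
    """
    if kd <= 0 or rate_ratio <= 0:
        raise ValueError("inputs must be positive")
    return kd / rate_ratio
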