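"""Constitutive relations of the lumped Hill-type muscle model.

The model consists of a contractile component (CC) in parallel with a
parallel elastic component (PEC), both in series with a series elastic
component (SEC) that represents tendon and aponeurosis and carries the
total muscle force:

    F_SEC = F_CC + F_PEC,      F_CC = A * F_im * f_l(l_CC) * f_v(v_CC)

where ``A`` is activation (first-order dynamics with time constant tau),
``f_l`` a piecewise-linear force-length factor and ``f_v`` the Hill
force-velocity hyperbola.  All lengths are in mm, forces in N, times in s;
CC velocities are expressed in optimal CC lengths per second (l_CCopt/s,
shortening positive).

Parameter records for the rabbit gastrocnemius (GAS), plantaris (PLA) and
soleus (SOL) are packaged as TOML fixtures, see :func:`load_fixture`.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "MuscleParameters",
    "ParameterError",
    "load_parameters",
    "load_fixture",
    "save_parameters",
    "fixture_names",
    "force_length",
    "force_velocity",
    "inverse_force_velocity",
    "eccentric_force_cap",
    "activation",
    "activation_rate",
    "sec_force",
    "sec_elongation",
    "sec_linear_stiffness",
    "pec_force",
    "pec_elongation",
    "cc_force",
    "csa_and_stress",
    "sec_strain_at_fim",
]


class ParameterError(ValueError):
    """A muscle parameter record violates its physical invariants."""


@dataclass(frozen=True)
class MuscleParameters:
    """One muscle's full Hill-model parameter record.

    Normalized force-length breakpoints ``l1 < l2 < 1 <= l3 < l4`` are
    fractions of the optimal CC length ``l_CCopt``; ``f_c`` is the force
    (fraction of F_im) at which the ascending limb changes slope.  The SEC
    force-elongation law is exponential up to the transition point
    (``F1_frac * F_im``, ``dlSEC1_frac * l_SEC0``) and linear with
    stiffness ``k`` beyond; if ``k`` is not stored it is derived from the
    stiffness-continuity constraint (:func:`sec_linear_stiffness`).
    """

    name: str
    F_im: float            # maximum isometric force, N
    l_CCopt: float         # optimal CC length, mm
    l1: float              # normalized force-length breakpoints [l_CCopt]
    l2: float
    l3: float
    l4: float
    f_c: float             # ascending-limb slope change force [F_im]
    v_CCmax: float         # maximal shortening speed [l_CCopt/s]
    curv: float            # Hill curvature a/F_im (dimensionless)
    tau: float             # activation time constant, s
    F1_frac: float         # SEC exponential-to-linear transition force [F_im]
    dlSEC1_frac: float     # SEC transition elongation [l_SEC0]
    k_sh: float            # SEC shape parameter (dimensionless)
    l_SEC0: float          # SEC slack length, mm
    k1: float              # PEC scale, N
    k2: float              # PEC exponent, 1/mm
    l_PEC0: float          # PEC slack length, mm
    mass: float            # muscle mass, g
    L_MTC_0: float         # reference muscle-tendon complex length, mm
    k: float | None = None         # SEC linear stiffness, N/mm (stored fit)
    l_fm: float | None = None      # mean fascicle length, mm
    density: float = 1.056         # tissue density, g/cm^3
    tau_off: float | None = None   # deactivation time constant (default: tau)
    ecc_slope_factor: float = 1.0  # eccentric slope / concentric slope at v=0 (C1 join)
    f_v_ecc_max: float = 1.5       # eccentric force-velocity asymptote [isometric]

    def __post_init__(self) -> None:
        self.validate()

    # -- derived conveniences -------------------------------------------------
    @property
    def F1(self) -> float:
        """SEC transition force, N."""
        return self.F1_frac * self.F_im

    @property
    def dlSEC1(self) -> float:
        """SEC transition elongation, mm."""
        return self.dlSEC1_frac * self.l_SEC0

    @property
    def k_eff(self) -> float:
        """SEC linear stiffness actually used, N/mm (stored value if present)."""
        return self.k if self.k is not None else sec_linear_stiffness(self)

    @property
    def tau_off_eff(self) -> float:
        return self.tau_off if self.tau_off is not None else self.tau

    def validate(self) -> None:
        if not (0.0 < self.l1 < self.l2 < 1.0 <= self.l3 < self.l4):
            raise ParameterError(
                f"{self.name}: breakpoints must satisfy 0 < l1 < l2 < 1 <= l3 < l4, "
                f"got {self.l1}, {self.l2}, {self.l3}, {self.l4}"
            )
        if not 0.0 < self.f_c < 1.0:
            raise ParameterError(f"{self.name}: f_c must lie in (0, 1)")
        positive = {
            "F_im": self.F_im, "l_CCopt": self.l_CCopt, "v_CCmax": self.v_CCmax,
            "curv": self.curv, "tau": self.tau, "k_sh": self.k_sh,
            "k2": self.k2, "l_SEC0": self.l_SEC0, "l_PEC0": self.l_PEC0,
            "mass": self.mass, "density": self.density, "L_MTC_0": self.L_MTC_0,
        }
        for key, value in positive.items():
            if not value > 0.0:
                raise ParameterError(f"{self.name}: {key} must be > 0, got {value}")
        if not 0.0 < self.F1_frac < 1.0:
            raise ParameterError(f"{self.name}: F1_frac must lie in (0, 1)")
        if not 0.0 < self.dlSEC1_frac < 1.0:
            raise ParameterError(f"{self.name}: dlSEC1_frac must lie in (0, 1)")
        if self.k1 < 0.0:
            raise ParameterError(f"{self.name}: k1 must be >= 0")
        if self.k is not None and self.k <= 0.0:
            raise ParameterError(f"{self.name}: stored k must be > 0")
        if self.f_v_ecc_max <= 1.0 or self.ecc_slope_factor <= 0.0:
            raise ParameterError(f"{self.name}: invalid eccentric extension parameters")

    def with_(self, **changes) -> "MuscleParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


# -- parameter I/O ------------------------------------------------------------

def load_parameters(path: str | Path) -> MuscleParameters:
    """Read a muscle parameter record from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(MuscleParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return MuscleParameters(**raw)


def save_parameters(p: MuscleParameters, path: str | Path) -> None:
    """Write a record in the same TOML dialect :func:`load_parameters` reads."""
    lines = [f'name = "{p.name}"']
    for f in fields(MuscleParameters):
        if f.name == "name":
            continue
        value = getattr(p, f.name)
        if value is None:
            continue
        lines.append(f"{f.name} = {float(value)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def fixture_names() -> list[str]:
    return ["gas", "pla", "sol"]


def load_fixture(name: str) -> MuscleParameters:
    """Load one of the packaged rabbit calf muscle records (gas, pla, sol)."""
    key = name.strip().lower()
    if key not in fixture_names():
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    ref = resources.files("hillcalf") / "fixtures" / f"{key}.toml"
    with ref.open("rb") as fh:
        raw = tomllib.load(fh)
    return MuscleParameters(**raw)


# -- constitutive relations ---------------------------------------------------

def force_length(l_cc_norm, p: MuscleParameters):
    """Piecewise-linear force-length factor f_l at normalized CC length.

    Zero outside [l1, l4]; rises with slope change at (l2, f_c); plateau of
    1 on [1, l3]; descends linearly to zero at l4.  Accepts scalars or
    arrays.
    """
    x = np.asarray(l_cc_norm, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized CC length must be >= 0")
    out = np.zeros_like(x)
    m1 = (x >= p.l1) & (x <= p.l2)
    out = np.where(m1, p.f_c * (x - p.l1) / (p.l2 - p.l1), out)
    m2 = (x > p.l2) & (x <= 1.0)
    out = np.where(m2, p.f_c + (1.0 - p.f_c) * (x - p.l2) / (1.0 - p.l2), out)
    m3 = (x > 1.0) & (x <= p.l3)
    out = np.where(m3, 1.0, out)
    m4 = (x > p.l3) & (x <= p.l4)
    out = np.where(m4, (p.l4 - x) / (p.l4 - p.l3), out)
    return float(out) if np.isscalar(l_cc_norm) else out


def _ecc_d(p: MuscleParameters) -> float:
    # Half-saturation lengthening speed of the eccentric hyperbola, chosen so
    # the slope at v=0 is ecc_slope_factor times the concentric slope there.
    conc_slope = (1.0 + 1.0 / p.curv) / p.v_CCmax
    return (p.f_v_ecc_max - 1.0) / (p.ecc_slope_factor * conc_slope)


def force_velocity(v, p: MuscleParameters):
    """Force-velocity factor f_v at CC velocity v (l_CCopt/s, shortening > 0).

    Concentric branch is the Hill hyperbola
    ``f_v = (v_CCmax - v) / (v_CCmax + v/curv)`` clamped to 0 beyond
    v_CCmax.  Negative v (lengthening) is routed to a Katz-style hyperbolic
    eccentric extension, continuous at v=0, saturating at ``f_v_ecc_max``;
    the eccentric branch is a modelling extension, not a measured relation.
    """
    vv = np.asarray(v, dtype=float)
    conc = (p.v_CCmax - vv) / (p.v_CCmax + vv / p.curv)
    conc = np.where(vv >= p.v_CCmax, 0.0, conc)
    d = _ecc_d(p)
    w = -vv  # lengthening speed
    ecc = p.f_v_ecc_max - (p.f_v_ecc_max - 1.0) * d / (d + w)
    out = np.where(vv >= 0.0, conc, ecc)
    return float(out) if np.isscalar(v) else out


def eccentric_force_cap(p: MuscleParameters) -> float:
    """Largest f_v the eccentric extension can deliver (its asymptote)."""
    return p.f_v_ecc_max


def inverse_force_velocity(f_v_target, p: MuscleParameters, with_flag: bool = False):
    """CC velocity (l_CCopt/s) that produces a given force-velocity factor.

    Analytic inverse of :func:`force_velocity` on both branches.  Targets at
    or above the eccentric asymptote saturate: the returned velocity is
    capped at ``-v_CCmax`` (fast lengthening) and, with ``with_flag=True``,
    a boolean saturation mask is returned alongside.
    """
    f = np.asarray(f_v_target, dtype=float)
    if np.any(f < 0.0):
        raise ValueError("f_v target must be >= 0")
    # concentric: f in [0, 1]
    v_conc = p.v_CCmax * (1.0 - f) / (1.0 + f / p.curv)
    # eccentric: f in (1, f_v_ecc_max)
    d = _ecc_d(p)
    fe = np.minimum(f, p.f_v_ecc_max * (1.0 - 1e-12))
    w = d * (fe - 1.0) / (p.f_v_ecc_max - fe)
    saturated = f >= p.f_v_ecc_max
    v_ecc = np.where(saturated, p.v_CCmax, w)
    v = np.where(f <= 1.0, v_conc, -v_ecc)
    if np.isscalar(f_v_target):
        v = float(v)
        saturated = bool(saturated)
    return (v, saturated) if with_flag else v


def activation(t, tau: float, a0: float = 0.0):
    """Closed-form activation 1 - (1 - a0) exp(-t/tau) for t >= 0."""
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    tt = np.asarray(t, dtype=float)
    out = 1.0 - (1.0 - a0) * np.exp(-tt / tau)
    return float(out) if np.isscalar(t) else out


def activation_rate(a: float, stim: bool, p: MuscleParameters) -> float:
    """ODE right-hand side dA/dt; decays to 0 with tau_off when stim is off."""
    if stim:
        return (1.0 - a) / p.tau
    return -a / p.tau_off_eff


def sec_linear_stiffness(p: MuscleParameters) -> float:
    """Linear-branch stiffness implied by stiffness continuity at dlSEC1.

    k = F1 * k_sh * e^{k_sh} / (dlSEC1 * (e^{k_sh} - 1)); the k_sh -> 0
    limit is F1/dlSEC1 (a purely linear spring).
    """
    if p.k_sh < 1e-8:
        return p.F1 / p.dlSEC1
    e = math.exp(p.k_sh)
    return p.F1 * p.k_sh * e / (p.dlSEC1 * (e - 1.0))


def sec_force(dl_sec, p: MuscleParameters, k: float | None = None):
    """SEC (tendon + aponeurosis) force at elongation dl_sec (mm).

    Exponential toe region up to (dlSEC1, F1), linear beyond with stiffness
    ``k`` (stored fit by default; pass ``k=sec_linear_stiffness(p)`` for the
    continuity-derived value).  Slack (dl <= 0) carries no force.
    """
    keff = p.k_eff if k is None else k
    dl = np.asarray(dl_sec, dtype=float)
    denom = math.expm1(p.k_sh)
    with np.errstate(over="ignore"):
        exp_branch = p.F1 / denom * np.expm1(p.k_sh * dl / p.dlSEC1)
    lin_branch = p.F1 + keff * (dl - p.dlSEC1)
    out = np.where(dl <= 0.0, 0.0, np.where(dl < p.dlSEC1, exp_branch, lin_branch))
    return float(out) if np.isscalar(dl_sec) else out


def sec_elongation(f_sec, p: MuscleParameters, k: float | None = None):
    """Inverse of :func:`sec_force`: elongation (mm) carrying force f_sec (N)."""
    keff = p.k_eff if k is None else k
    f = np.asarray(f_sec, dtype=float)
    if np.any(f < -1e-12):
        raise ValueError("SEC force must be >= 0")
    denom = math.expm1(p.k_sh)
    exp_branch = p.dlSEC1 / p.k_sh * np.log1p(np.maximum(f, 0.0) * denom / p.F1)
    lin_branch = p.dlSEC1 + (f - p.F1) / keff
    out = np.where(f <= 0.0, 0.0, np.where(f < p.F1, exp_branch, lin_branch))
    return float(out) if np.isscalar(f_sec) else out


def pec_force(dl_pec, p: MuscleParameters):
    """PEC force k1*(e^{k2*dl} - 1) at elongation dl_pec (mm); 0 when slack."""
    dl = np.asarray(dl_pec, dtype=float)
    with np.errstate(over="ignore"):
        out = np.where(dl > 0.0, p.k1 * np.expm1(p.k2 * np.maximum(dl, 0.0)), 0.0)
    return float(out) if np.isscalar(dl_pec) else out


def pec_elongation(f_pec, p: MuscleParameters):
    """Inverse of :func:`pec_force` (requires k1 > 0 for nonzero forces)."""
    f = np.asarray(f_pec, dtype=float)
    if np.any(f < -1e-12):
        raise ValueError("PEC force must be >= 0")
    if p.k1 == 0.0:
        if np.any(f > 0):
            raise ValueError("PEC with k1=0 cannot carry force")
        return 0.0 if np.isscalar(f_pec) else np.zeros_like(f)
    out = np.where(f <= 0.0, 0.0, np.log1p(np.maximum(f, 0.0) / p.k1) / p.k2)
    return float(out) if np.isscalar(f_pec) else out


def cc_force(a, l_cc_norm, v, p: MuscleParameters):
    """Active CC force A * F_im * f_l * f_v (N)."""
    aa = np.asarray(a, dtype=float)
    if np.any((aa < -1e-12) | (aa > 1.0 + 1e-12)):
        raise ValueError("activation must lie in [0, 1]")
    out = aa * p.F_im * force_length(l_cc_norm, p) * force_velocity(v, p)
    return float(out) if np.isscalar(a) and np.isscalar(l_cc_norm) and np.isscalar(v) else out


def csa_and_stress(p: MuscleParameters) -> tuple[float, float]:
    """Physiological cross-sectional area (cm^2) and mean stress (N/cm^2).

    CSA = mass / (density * l_CCopt) with l_CCopt in cm; stress = F_im/CSA.
    """
    csa = p.mass / (p.density * (p.l_CCopt / 10.0))
    return csa, p.F_im / csa


def sec_strain_at_fim(p: MuscleParameters) -> float:
    """SEC strain at maximum isometric force, as a fraction of l_SEC0."""
    return sec_elongation(p.F_im, p) / p.l_SEC0
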