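"""Forward dynamics of the CC-SEC-PEC chain under in-situ protocols.

The muscle-tendon complex (MTC) is modelled quasi-statically: the only
mechanical state is the CC length, advanced by converting the force the
SEC/PEC balance demands from the CC into a CC velocity through the inverse
force-velocity relation.  Activation follows first-order dynamics and is
evaluated in closed form.  Protocols are either length-controlled (the
lever imposes l_MTC(t)) or force-controlled (the lever moves so that the
total force stays clamped), mirroring the isometric / isotonic /
isokinetic contractions used to characterize the rabbit calf muscles
in situ.

Geometry (all mm): ``l_MTC = l_SEC0 + dl_SEC + l_CC``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .muscle_model import (
    MuscleParameters,
    cc_force,
    force_length,
    pec_force,
    sec_elongation,
    sec_force,
)

__all__ = [
    "ProtocolSpec",
    "SimulationTrace",
    "ProtocolError",
    "SimulationError",
    "equilibrium_cc_length",
    "passive_force_at_length",
    "optimal_mtc_length",
    "simulate",
    "simulate_isometric_series",
    "force_balance_residual",
]

Mode = Literal["isometric", "isotonic_afterload", "isokinetic_ramp", "quick_release"]

#: force scale (fraction of F_im) of the bounded relaxation law used for
#: an effectively inactive CC
REGULARIZATION_EPS = 1e-3
#: drive A*f_l (fraction of F_im) below which the CC is treated as inactive
#: and the force-velocity inversion is replaced by the relaxation law
DRIVE_FLOOR = 1e-7


class ProtocolError(ValueError):
    """Protocol specification invalid or outside model validity."""


class SimulationError(RuntimeError):
    """Solver failure or physically unattainable demand."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one contraction experiment.

    ``ramp_velocity`` is signed (positive = lengthening) in mm/s and the
    ramp fields are required only for the ramp modes.  ``afterload`` (N) is
    required for isotonic mode; the lever switches from length clamp to
    force clamp either at ``release_time`` (s) or, if that is None, when
    the total force first reaches the afterload.
    """

    mode: Mode
    l_MTC_start: float                 # mm
    stimulation_on: float = 0.1        # s
    stimulation_off: float = 0.8       # s
    total_duration: float = 1.0        # s
    sample_rate: float = 1000.0        # Hz
    ramp_velocity: float | None = None # mm/s, + = lengthening
    ramp_length: float | None = None   # mm (magnitude of imposed excursion)
    ramp_start: float | None = None    # s
    afterload: float | None = None     # N
    release_time: float | None = None  # s (isotonic: timed release from plateau)
    label: str = ""

    def __post_init__(self) -> None:
        if self.total_duration <= 0 or self.sample_rate <= 0:
            raise ProtocolError("durations and sample rate must be > 0")
        if not 0 <= self.stimulation_on < self.stimulation_off:
            raise ProtocolError("need 0 <= stimulation_on < stimulation_off")
        if self.mode in ("isokinetic_ramp", "quick_release"):
            if self.ramp_velocity is None or self.ramp_length is None or self.ramp_start is None:
                raise ProtocolError(f"{self.mode} requires ramp_velocity, ramp_length, ramp_start")
            if self.ramp_velocity == 0 or self.ramp_length <= 0:
                raise ProtocolError("ramp_velocity must be nonzero and ramp_length > 0")
        elif self.ramp_velocity is not None or self.ramp_length is not None:
            raise ProtocolError(f"ramp fields are only valid for ramp modes, not {self.mode}")
        if self.mode == "isotonic_afterload":
            if self.afterload is None or self.afterload <= 0:
                raise ProtocolError("isotonic mode requires afterload > 0")
        elif self.afterload is not None:
            raise ProtocolError("afterload is only valid for isotonic mode")

    @property
    def ramp_duration(self) -> float:
        return abs(self.ramp_length / self.ramp_velocity)

    @property
    def ramp_end(self) -> float:
        return self.ramp_start + self.ramp_duration

    def l_mtc_of_t(self, t: float) -> float:
        """Imposed MTC length during length-controlled operation."""
        if self.mode in ("isokinetic_ramp", "quick_release") and t > self.ramp_start:
            dt = min(t, self.ramp_end) - self.ramp_start
            return self.l_MTC_start + math.copysign(1.0, self.ramp_velocity) * abs(self.ramp_velocity) * dt
        return self.l_MTC_start


@dataclass
class SimulationTrace:
    """Uniformly sampled record of one simulated contraction."""

    t: np.ndarray        # s
    l_MTC: np.ndarray    # mm
    l_CC: np.ndarray     # mm
    dl_SEC: np.ndarray   # mm
    F_total: np.ndarray  # N (= SEC force)
    F_PEC: np.ndarray    # N
    A: np.ndarray        # activation
    stim: np.ndarray     # bool
    v_CC: np.ndarray     # l_CCopt/s, shortening positive
    sat: np.ndarray      # bool, force-velocity inversion saturated
    meta: dict = field(default_factory=dict)

    COLUMNS = ("t", "l_MTC", "l_CC", "dl_SEC", "F_total", "F_PEC", "A", "stim", "v_CC", "sat")

    def to_frame(self) -> pd.DataFrame:
        data = {c: getattr(self, c) for c in self.COLUMNS}
        df = pd.DataFrame(data)
        df["stim"] = df["stim"].astype(int)
        df["sat"] = df["sat"].astype(int)
        return df

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, meta: dict | None = None) -> "SimulationTrace":
        df = pd.read_csv(path)
        missing = [c for c in ("t", "l_MTC", "F_total") if c not in df.columns]
        if missing:
            raise ValueError(f"trace file lacks required columns {missing}")
        kwargs = {}
        n = len(df)
        for c in cls.COLUMNS:
            if c in df.columns:
                arr = df[c].to_numpy()
            elif c in ("stim", "sat"):
                arr = np.zeros(n, dtype=bool)
            else:
                arr = np.full(n, np.nan)
            if c in ("stim", "sat"):
                arr = arr.astype(bool)
            kwargs[c] = arr
        return cls(meta=meta or {}, **kwargs)

    def copy(self) -> "SimulationTrace":
        return SimulationTrace(
            **{c: getattr(self, c).copy() for c in self.COLUMNS}, meta=dict(self.meta)
        )

    def __len__(self) -> int:
        return len(self.t)


# -- static balance -----------------------------------------------------------

def _balance(l_cc: float, l_mtc: float, a: float, p: MuscleParameters) -> float:
    f_sec = sec_force(l_mtc - l_cc - p.l_SEC0, p)
    f_cc = a * p.F_im * force_length(l_cc / p.l_CCopt, p)  # v = 0
    return f_sec - f_cc - pec_force(l_cc - p.l_PEC0, p)


def equilibrium_cc_length(
    l_mtc: float, a: float, p: MuscleParameters, full: bool = False
):
    """Static CC length solving the isometric force balance at activation a.

    Returns the root of ``F_SEC(dl_SEC) = F_CC(v=0) + F_PEC``; for MTC
    lengths where the whole chain is slack the zero-force solution
    ``l_CC = l_MTC - l_SEC0`` is returned (flagged when ``full=True``).
    """
    hi = l_mtc - p.l_SEC0
    if hi <= 0:
        raise ProtocolError(f"l_MTC={l_mtc} shorter than SEC slack length {p.l_SEC0}")
    if abs(_balance(hi, l_mtc, a, p)) < 1e-12:
        return (hi, True) if full else hi
    lo = 1e-9
    l_cc = brentq(_balance, lo, hi, args=(l_mtc, a, p), xtol=1e-12, rtol=1e-14)
    resid = _balance(l_cc, l_mtc, a, p)
    if abs(resid) > 1e-6:
        raise SimulationError(f"equilibrium residual {resid:.3g} N at l_MTC={l_mtc}")
    return (l_cc, False) if full else l_cc


def passive_force_at_length(l_mtc: float, p: MuscleParameters) -> float:
    """Steady passive (unstimulated) force at MTC length l_mtc."""
    l_cc = equilibrium_cc_length(l_mtc, 0.0, p)
    return sec_force(l_mtc - l_cc - p.l_SEC0, p)


def optimal_mtc_length(p: MuscleParameters) -> float:
    """MTC length at which the fully active CC sits exactly at l_CCopt."""
    f_tot = p.F_im + pec_force(p.l_CCopt - p.l_PEC0, p)
    return p.l_SEC0 + sec_elongation(f_tot, p) + p.l_CCopt


# -- activation ---------------------------------------------------------------

def _activation_of_t(t: float, proto: ProtocolSpec, p: MuscleParameters) -> float:
    if t <= proto.stimulation_on:
        return 0.0
    if t <= proto.stimulation_off:
        return 1.0 - math.exp(-(t - proto.stimulation_on) / p.tau)
    a_off = 1.0 - math.exp(-(proto.stimulation_off - proto.stimulation_on) / p.tau)
    return a_off * math.exp(-(t - proto.stimulation_off) / p.tau_off_eff)


# -- CC velocity law ----------------------------------------------------------

def _cc_velocity(f_req: float, denom: float, p: MuscleParameters) -> tuple[float, bool]:
    """CC velocity (l_CCopt/s) delivering force f_req at drive denom = A*F_im*f_l.

    Exact inverse of the force-velocity relation on both branches; when the
    drive is degenerate (below REGULARIZATION_EPS * F_im) a bounded linear
    relaxation law replaces the ill-conditioned inversion.  Returns
    (velocity, saturated).
    """
    if denom < DRIVE_FLOOR * p.F_im:
        # inactive CC: relax toward the passive balance at bounded speed
        eps = REGULARIZATION_EPS * p.F_im
        v = -p.v_CCmax * max(-1.0, min(1.0, f_req / eps))
        return v, abs(f_req) > 1e-4
    fv = f_req / denom
    if fv <= 0.0:
        # a negative demand (stretched PEC against a slack SEC) cannot be
        # balanced by the contractile element; shorten at the speed cap
        return p.v_CCmax, f_req < -1e-4
    if fv <= 1.0:
        return p.v_CCmax * (1.0 - fv) / (1.0 + fv / p.curv), False
    if fv < p.f_v_ecc_max:
        d = (p.f_v_ecc_max - 1.0) * p.curv * p.v_CCmax / (p.ecc_slope_factor * (p.curv + 1.0))
        w = d * (fv - 1.0) / (p.f_v_ecc_max - fv)
        return -min(w, p.v_CCmax), False
    return -p.v_CCmax, True


def _rhs_length(t: float, l_cc: float, proto: ProtocolSpec, p: MuscleParameters) -> float:
    l_mtc = proto.l_mtc_of_t(t)
    f_req = sec_force(l_mtc - l_cc - p.l_SEC0, p) - pec_force(l_cc - p.l_PEC0, p)
    a = _activation_of_t(t, proto, p)
    denom = a * p.F_im * force_length(l_cc / p.l_CCopt, p)
    v, _ = _cc_velocity(f_req, denom, p)
    return -v * p.l_CCopt


def _rhs_force(t: float, l_cc: float, f_clamp: float, proto: ProtocolSpec, p: MuscleParameters) -> float:
    f_req = f_clamp - pec_force(l_cc - p.l_PEC0, p)
    a = _activation_of_t(t, proto, p)
    denom = a * p.F_im * force_length(l_cc / p.l_CCopt, p)
    v, _ = _cc_velocity(f_req, denom, p)
    return -v * p.l_CCopt


# -- main driver --------------------------------------------------------------

@dataclass
class _Phase:
    t0: float
    t1: float
    control: str                       # "length" | "force"
    f_clamp: float | None = None
    l_hold: float | None = None        # fixed MTC length after a clamp ends
    sol: object = None                 # dense ODE solution


def _integrate_phase(rhs: Callable, t0: float, t1: float, y0: float, max_step: float):
    if t1 - t0 < 1e-12:
        return None, y0
    sol = solve_ivp(
        rhs, (t0, t1), [y0], method="LSODA",
        rtol=1e-10, atol=1e-11, max_step=max_step, dense_output=True,
    )
    if not sol.success:
        raise SimulationError(f"integration failed on [{t0}, {t1}]: {sol.message}")
    return sol, float(sol.y[0, -1])


def simulate(
    proto: ProtocolSpec, p: MuscleParameters, max_step: float | None = None,
) -> SimulationTrace:
    """Run one protocol and return the sampled trace.

    The CC starts from the passive static equilibrium at the start length.
    Isotonic mode holds the length until the release (timed, or triggered
    by the force reaching the afterload), then clamps the total force; if
    the CC can no longer shorten against the load the clamp disengages and
    the length is held.
    """
    t_end = proto.total_duration
    l_cc0 = equilibrium_cc_length(proto.l_MTC_start, 0.0, p)
    if max_step is None:
        max_step = min(5e-3, p.tau / 4.0)

    # --- break the timeline into smooth phases
    phases: list[_Phase] = []
    if proto.mode == "isometric":
        cuts = [0.0, proto.stimulation_on, min(proto.stimulation_off, t_end), t_end]
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                phases.append(_Phase(a, b, "length"))
    elif proto.mode in ("isokinetic_ramp", "quick_release"):
        if proto.ramp_end > t_end:
            raise ProtocolError("ramp extends past total_duration")
        cuts = sorted({0.0, proto.stimulation_on, proto.ramp_start, proto.ramp_end,
                       min(proto.stimulation_off, t_end), t_end})
        cuts = [c for c in cuts if 0.0 <= c <= t_end]
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                phases.append(_Phase(a, b, "length"))
    elif proto.mode == "isotonic_afterload":
        phases = None  # handled below (event-driven)
    else:  # pragma: no cover - guarded by ProtocolSpec
        raise ProtocolError(f"unknown mode {proto.mode}")

    solutions: list[_Phase] = []
    y = l_cc0
    if phases is not None:
        for ph in phases:
            sol, y = _integrate_phase(
                lambda t, lcc: _rhs_length(t, lcc[0] if np.ndim(lcc) else lcc, proto, p),
                ph.t0, ph.t1, y, max_step)
            ph.sol = sol
            solutions.append(ph)
    else:
        solutions, y = _simulate_isotonic(proto, p, l_cc0, max_step)

    return _sample(proto, p, solutions)


def _simulate_isotonic(proto, p, l_cc0, max_step):
    t_end = proto.total_duration
    afterload = proto.afterload
    f_max = p.F_im + pec_force(p.l_CCopt - p.l_PEC0, p)
    if afterload >= f_max:
        raise ProtocolError(
            f"afterload {afterload} N exceeds the maximum attainable force {f_max:.1f} N")

    solutions: list[_Phase] = []
    y = l_cc0

    def rhs_len(t, lcc):
        return _rhs_length(t, float(lcc[0]), proto, p)

    def force_event(t, lcc):
        return (sec_force(proto.l_MTC_start - float(lcc[0]) - p.l_SEC0, p) - afterload)

    force_event.terminal = True
    force_event.direction = 1.0

    # phase 1: length clamp until release
    t_release = proto.release_time if proto.release_time is not None else t_end
    cuts = sorted({0.0, proto.stimulation_on, min(t_release, t_end)})
    t_cur = 0.0
    released_at = None
    for a, b in zip(cuts, cuts[1:]):
        if b <= a:
            continue
        events = force_event if proto.release_time is None and a >= proto.stimulation_on else None
        sol = solve_ivp(rhs_len, (a, b), [y], method="LSODA", rtol=1e-10, atol=1e-11,
                        max_step=max_step, dense_output=True, events=events)
        if not sol.success:
            raise SimulationError(sol.message)
        ph = _Phase(a, float(sol.t[-1]), "length")
        ph.sol = sol
        solutions.append(ph)
        y = float(sol.y[0, -1])
        t_cur = float(sol.t[-1])
        if events is not None and sol.t_events[0].size:
            released_at = t_cur
            break
    if proto.release_time is not None and t_release < t_end:
        released_at = t_release
    if released_at is None:
        if proto.release_time is None:
            raise SimulationError(
                f"force never reached the afterload {afterload} N before t={t_end}")
        return solutions, y

    # check that the release steps the force down (quick release from plateau)
    def rhs_clamp(t, lcc):
        return _rhs_force(t, float(lcc[0]), afterload, proto, p)

    def stall_event(t, lcc):
        lcc0 = float(lcc[0])
        f_req = afterload - pec_force(lcc0 - p.l_PEC0, p)
        a = _activation_of_t(t, proto, p)
        denom = a * p.F_im * force_length(lcc0 / p.l_CCopt, p)
        return f_req - 0.999 * max(denom, 1e-12)

    stall_event.terminal = True
    stall_event.direction = 1.0

    # phase 2: force clamp until stall / stim off / end
    t_stop = min(proto.stimulation_off, t_end)
    sol = solve_ivp(rhs_clamp, (released_at, t_stop), [y], method="LSODA",
                    rtol=1e-10, atol=1e-11, max_step=max_step,
                    dense_output=True, events=stall_event)
    if not sol.success:
        raise SimulationError(sol.message)
    ph = _Phase(released_at, float(sol.t[-1]), "force", f_clamp=afterload)
    ph.sol = sol
    solutions.append(ph)
    y = float(sol.y[0, -1])
    t_cur = float(sol.t[-1])

    # phase 3: hold length at wherever the lever stopped
    if t_cur < t_end:
        l_hold = p.l_SEC0 + sec_elongation(afterload, p) + y
        hold_proto = ProtocolSpec(
            mode="isometric", l_MTC_start=l_hold,
            stimulation_on=proto.stimulation_on, stimulation_off=proto.stimulation_off,
            total_duration=proto.total_duration, sample_rate=proto.sample_rate)
        cuts = sorted({t_cur, min(proto.stimulation_off, t_end), t_end})
        for a, b in zip(cuts, cuts[1:]):
            if b <= a:
                continue
            sol, y = _integrate_phase(
                lambda t, lcc: _rhs_length(t, float(lcc[0]), hold_proto, p),
                a, b, y, max_step)
            ph = _Phase(a, b, "length", l_hold=l_hold)
            ph.sol = sol
            solutions.append(ph)
    return solutions, y


def _sample(proto: ProtocolSpec, p: MuscleParameters, phases: list[_Phase]) -> SimulationTrace:
    dt = 1.0 / proto.sample_rate
    n = int(math.floor(proto.total_duration / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    n = len(t)
    l_cc = np.empty(n)
    l_mtc = np.empty(n)
    v_cc = np.empty(n)
    sat = np.zeros(n, dtype=bool)

    for i, ti in enumerate(t):
        ph = None
        for cand in phases:
            if cand.t0 - 1e-12 <= ti <= cand.t1 + 1e-12:
                ph = cand  # later phases win at boundaries
        if ph is None:
            ph = phases[-1]
        ti_c = min(max(ti, ph.t0), ph.t1)
        if ph.sol is not None:
            lcc_i = float(ph.sol.sol(ti_c)[0])
        else:
            lcc_i = float("nan")
        l_cc[i] = lcc_i
        if ph.control == "force":
            l_mtc[i] = p.l_SEC0 + sec_elongation(ph.f_clamp, p) + lcc_i
            f_req = ph.f_clamp - pec_force(lcc_i - p.l_PEC0, p)
        else:
            l_mtc[i] = ph.l_hold if ph.l_hold is not None else proto.l_mtc_of_t(ti_c)
            f_req = (sec_force(l_mtc[i] - lcc_i - p.l_SEC0, p)
                     - pec_force(lcc_i - p.l_PEC0, p))
        a_i = _activation_of_t(ti_c, proto, p)
        denom = a_i * p.F_im * force_length(lcc_i / p.l_CCopt, p)
        v_cc[i], sat[i] = _cc_velocity(f_req, denom, p)

    dl_sec = l_mtc - l_cc - p.l_SEC0
    f_total = sec_force(dl_sec, p)
    f_pec = pec_force(l_cc - p.l_PEC0, p)
    a = np.array([_activation_of_t(ti, proto, p) for ti in t])
    stim = (t >= proto.stimulation_on) & (t < proto.stimulation_off)
    meta = {"protocol": proto, "muscle": p.name}
    return SimulationTrace(t=t, l_MTC=l_mtc, l_CC=l_cc, dl_SEC=dl_sec,
                           F_total=f_total, F_PEC=f_pec, A=a, stim=stim,
                           v_CC=v_cc, sat=sat, meta=meta)


def simulate_isometric_series(
    lengths, p: MuscleParameters, passive_only: bool = False,
    passive_cap_frac: float = 0.2, stim_duration: float = 0.8,
) -> list[tuple[float, float, float]]:
    """Steady active and passive forces over a series of MTC lengths.

    The series is truncated where the passive force exceeds
    ``passive_cap_frac * F_im`` (the muscles were not stretched beyond
    about 0.2 F_im in situ to avoid damage).  Returns a list of
    (l_MTC, F_steady, F_passive); active steady forces come from the
    static equilibrium, which the dynamic solver matches to <0.5%.
    """
    lengths = sorted(float(x) for x in lengths)
    out: list[tuple[float, float, float]] = []
    for l_mtc in lengths:
        f_pass = passive_force_at_length(l_mtc, p)
        if f_pass > passive_cap_frac * p.F_im:
            break
        if passive_only:
            out.append((l_mtc, f_pass, f_pass))
            continue
        l_cc = equilibrium_cc_length(l_mtc, 1.0, p)
        f_act = sec_force(l_mtc - l_cc - p.l_SEC0, p)
        out.append((l_mtc, f_act, f_pass))
    if not out:
        raise ProtocolError("isometric series empty after passive-force truncation")
    return out


def force_balance_residual(trace: SimulationTrace, p: MuscleParameters) -> np.ndarray:
    """Per-sample residual of the force identity F_SEC - F_CC - F_PEC (N)."""
    f_cc = cc_force(np.clip(trace.A, 0.0, 1.0),
                    trace.l_CC / p.l_CCopt, trace.v_CC, p)
    return trace.F_total - f_cc - trace.F_PEC
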