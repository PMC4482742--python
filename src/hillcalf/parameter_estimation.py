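"""Recovery of Hill-model parameters from in-situ style recordings.

The pipeline mirrors the four in-situ determinations and runs them in
dependency order:

1. series elasticity (SEC) from the fast isokinetic release, correcting
   the lever displacement for fiber shortening;
2. parallel elasticity (PEC) from the passive length sweep, attributing
   the passive lever force to the PEC after subtracting the SEC stretch
   at the measured force;
3. active force-length relation from the isometric series, recovering CC
   lengths through the fitted SEC inverse;
4. force-velocity relation from the after-loaded isotonic releases; and
5. the activation time constant from the tetanic force rise at optimum.

Estimators consume only measurable channels (time, lever position, force,
stimulation flag), protocol metadata and the anatomical measurements
carried by the experiment set; latent simulator state is never read.  The
anatomically measured series-elastic rest length anchors the absolute
CC/SEC length split, which force-length-time data alone cannot identify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares
from scipy.signal import savgol_filter

from .muscle_model import MuscleParameters
from .contraction_simulator import ProtocolSpec, SimulationTrace
from .synthetic_experiments import ExperimentSet

__all__ = [
    "EstimationError",
    "SECFit",
    "PECFit",
    "ForceLengthFit",
    "ForceVelocityFit",
    "EstimationReport",
    "fit_sec",
    "fit_passive",
    "fit_force_length",
    "fit_force_velocity",
    "fit_hill_hyperbola",
    "fit_activation_tau",
    "steady_forces_from_trace",
    "estimate_all",
    "effect_size",
    "EffectSize",
]


class EstimationError(RuntimeError):
    """A fitting stage cannot run (bad inputs, too few usable trials, ...)."""


# -- fitted-component containers ---------------------------------------------

@dataclass
class SECFit:
    F1: float          # N
    dlSEC1: float      # mm
    k_sh: float
    k: float           # N/mm
    l_SEC0: float      # mm (anatomical anchor, echoed)
    residual: float = 0.0
    n_iter: int = 0
    n_points: int = 0

    def force(self, dl):
        dl = np.asarray(dl, dtype=float)
        exp_b = self.F1 / math.expm1(self.k_sh) * np.expm1(self.k_sh * dl / self.dlSEC1)
        lin_b = self.F1 + self.k * (dl - self.dlSEC1)
        out = np.where(dl <= 0, 0.0, np.where(dl < self.dlSEC1, exp_b, lin_b))
        return out if out.ndim else float(out)

    def elongation(self, f):
        f = np.asarray(f, dtype=float)
        exp_b = self.dlSEC1 / self.k_sh * np.log1p(np.maximum(f, 0.0) * math.expm1(self.k_sh) / self.F1)
        lin_b = self.dlSEC1 + (f - self.F1) / self.k
        out = np.where(f <= 0, 0.0, np.where(f < self.F1, exp_b, lin_b))
        return out if out.ndim else float(out)


@dataclass
class PECFit:
    k1: float          # N
    k2: float          # 1/mm
    l_PEC0: float      # mm (absolute CC length at which the PEC engages)
    residual: float = 0.0
    n_points: int = 0
    slack: bool = False    # all passive forces were ~0

    def force(self, l_cc):
        dl = np.asarray(l_cc, dtype=float) - self.l_PEC0
        out = np.where(dl > 0, self.k1 * np.expm1(self.k2 * np.clip(dl, 0, None)), 0.0)
        return out if out.ndim else float(out)


@dataclass
class ForceLengthFit:
    F_im: float
    l_CCopt: float
    l1: float
    l2: float
    l3: float
    l4: float
    f_c: float
    residual: float = 0.0
    n_points: int = 0
    n_descending: int = 0
    low_confidence_descending: bool = False

    def factor(self, l_cc_norm):
        x = np.asarray(l_cc_norm, dtype=float)
        out = np.zeros_like(x)
        out = np.where((x >= self.l1) & (x <= self.l2),
                       self.f_c * (x - self.l1) / (self.l2 - self.l1), out)
        out = np.where((x > self.l2) & (x <= 1.0),
                       self.f_c + (1 - self.f_c) * (x - self.l2) / (1 - self.l2), out)
        out = np.where((x > 1.0) & (x <= self.l3), 1.0, out)
        out = np.where((x > self.l3) & (x <= self.l4),
                       (self.l4 - x) / (self.l4 - self.l3), out)
        return out if out.ndim else float(out)


@dataclass
class ForceVelocityFit:
    v_CCmax: float     # l_CCopt/s
    curv: float
    residual: float = 0.0
    n_pairs: int = 0
    n_trials_used: int = 0
    trials_excluded: list = field(default_factory=list)

    def factor(self, v_norm):
        v = np.asarray(v_norm, dtype=float)
        out = np.clip((self.v_CCmax - v) / (self.v_CCmax + v / self.curv), 0.0, None)
        return out if out.ndim else float(out)


@dataclass
class EstimationReport:
    muscle: str
    params: MuscleParameters | None
    sec: SECFit | None = None
    pec: PECFit | None = None
    force_length: ForceLengthFit | None = None
    force_velocity: ForceVelocityFit | None = None
    tau: float | None = None
    tau_residual: float | None = None
    recovery_errors_pct: dict | None = None
    stage_errors: dict = field(default_factory=dict)
    seed: int | None = None
    noise: object = None


# -- helpers ------------------------------------------------------------------

def _noise_sd_estimate(trace: SimulationTrace) -> float:
    """Force-noise SD estimated from the pre-stimulation window."""
    proto: ProtocolSpec = trace.meta.get("protocol")
    if proto is None:
        mask = trace.t < trace.t[len(trace.t) // 20]
    else:
        mask = trace.t < proto.stimulation_on - 0.005
    if mask.sum() < 8:
        return 0.0
    return float(np.std(trace.F_total[mask]))


def _maybe_smooth(y: np.ndarray, noisy: bool, window: int = 31, order: int = 3) -> np.ndarray:
    if not noisy or len(y) < 12:
        return y
    w = min(window, len(y) - (1 - len(y) % 2))
    if w % 2 == 0:
        w -= 1
    if w <= order + 1:
        return y
    return savgol_filter(y, w, order)


# -- stage 1: series elasticity ----------------------------------------------

def fit_sec(
    trace: SimulationTrace,
    l_SEC0: float,
    isotonic_trials: Sequence[SimulationTrace] = (),
    passive_points: np.ndarray | None = None,
    v_CCmax_bound: float | None = None,
    n_iter: int = 8,
) -> SECFit:
    """Series-elastic force-elongation law, accounting for fiber motion.

    Primary method (when after-loaded releases are available): at each
    force step from the tetanic plateau to an afterload the lever jumps
    instantaneously while the fibers, speed-limited, have not moved — the
    jump equals the SEC elongation difference between the two forces
    exactly.  The SEC law is fitted to the jump-vs-load set; because the
    jumps constrain only elongation differences over the afterload range,
    the toe below the lowest afterload is then pinned by a local joint
    refinement against the passive length sweep (SEC in series with the
    parallel elastic spring), when ``passive_points`` are available.

    Fallback (fast isokinetic release only): the release, faster than the
    CC can shorten, discharges the SEC while the fibers move little; the
    lever displacement corrected for a capped-speed fiber-shortening
    estimate maps the curve approximately (iterated to self-consistency).
    ``v_CCmax_bound`` (mm/s) defaults to half the ramp speed, which the
    protocol guarantees to exceed the CC speed limit.
    """
    if isotonic_trials:
        fit = _fit_sec_from_steps(isotonic_trials, l_SEC0, passive_points)
        fit.l_SEC0 = l_SEC0
        return fit
    return _fit_sec_from_release(trace, l_SEC0, v_CCmax_bound, n_iter)


def _fit_sec_from_steps(
    trials: Sequence[SimulationTrace],
    l_SEC0: float,
    passive_points: np.ndarray | None = None,
) -> SECFit:
    loads, plateaus, jumps = [], [], []
    for tr in trials:
        proto: ProtocolSpec = tr.meta.get("protocol")
        if proto is None or proto.afterload is None:
            continue
        sd = _noise_sd_estimate(tr)
        t_rel = proto.release_time
        if t_rel is None:
            i_step = int(np.argmax(np.abs(np.diff(tr.l_MTC))))
            t_rel = float(tr.t[i_step + 1])
        pre = (tr.t >= t_rel - 0.03) & (tr.t < t_rel - 1e-9)
        tol = max(0.01 * proto.afterload, 3 * sd)
        post = (tr.t >= t_rel - 1e-9) & (tr.t <= t_rel + 0.012) \
            & (np.abs(tr.F_total - proto.afterload) <= tol)
        if pre.sum() < 4 or post.sum() < 5:
            continue
        dt = float(np.median(np.diff(tr.t)))
        i_rel = int(np.argmin(np.abs(tr.t - t_rel)))
        if abs(tr.t[i_rel] - t_rel) < 0.5 * dt and post[i_rel]:
            l_post = float(tr.l_MTC[i_rel])   # sample lands on the step
        else:
            coef = np.polyfit(tr.t[post] - t_rel, tr.l_MTC[post], 3)
            l_post = float(np.polyval(coef, 0.0))
        # the pre-release force still creeps toward the tetanic plateau:
        # the jump maps g(load) - g(F at the release instant), so F0 is
        # extrapolated to t_rel (the lever itself is clamped, hence exact)
        cf = np.polyfit(tr.t[pre] - t_rel, tr.F_total[pre], 3)
        jumps.append(l_post - float(np.median(tr.l_MTC[pre])))
        loads.append(proto.afterload)
        plateaus.append(float(np.polyval(cf, 0.0)))
    if len(loads) < 4:
        raise EstimationError(
            f"only {len(loads)} usable force steps for the SEC fit (need >= 4)")
    loads = np.asarray(loads)
    plateaus = np.asarray(plateaus)
    jumps = np.asarray(jumps)
    f0 = float(plateaus.max())

    sd = float(np.mean([_noise_sd_estimate(tr) for tr in trials]))

    def stiffening_penalty(x):
        # tendon stiffness must not drop at the exponential-to-linear
        # transition: k >= toe-end stiffness F1*k_sh*e^k_sh/(dl1*(e^k_sh-1)).
        # Without this, a second exact interpolant exists that rejoins the
        # linear branch where the toe curve re-crosses it.
        k_cont = x[0] * x[2] * math.exp(x[2]) / (x[1] * math.expm1(x[2]))
        return 10.0 * math.sqrt(len(loads)) * max(0.0, (k_cont - x[3]) / x[3])

    def resid(x):
        m = SECFit(F1=x[0], dlSEC1=x[1], k_sh=x[2], k=x[3], l_SEC0=0.0)
        r = (m.elongation(loads) - m.elongation(plateaus)) - jumps
        return np.append(r, stiffening_penalty(x))

    # stage A: jump differences alone; tendon-strain and shape bounds keep
    # the weakly constrained toe from running away under noise
    span = float(jumps.max() - jumps.min())
    k0 = (plateaus.max() - loads.min()) / max(span, 1e-6)
    lb = [1e-9, 1e-6, 0.2, 1e-6]
    ub = [0.95 * f0, 0.15 * l_SEC0, 6.0, np.inf]
    best = None
    for frac, ksh in ((0.31, 2.2), (0.4, 2.7), (0.25, 1.6), (0.5, 3.3), (0.35, 1.0)):
        x0 = np.clip([frac * f0, frac * span, ksh, k0], lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise EstimationError("SEC step fit failed from all starts")

    # The transition force F1 can be indeterminate within the load-free
    # interval around it: the exponential toe and the linear branch can be
    # rejoined at any force between the two neighbouring afterloads with
    # an (essentially) identical curve.  Profile the cost over F1 and
    # report the midpoint of the flat interval; where F1 is well
    # identified the interval collapses onto the optimum.
    x_best = best.x

    def profile(f1v: float):
        def r3(y):
            return resid(np.concatenate([[f1v], y]))
        sol = least_squares(r3, x_best[1:], bounds=(lb[1:], ub[1:]),
                            xtol=2.3e-16, ftol=2.3e-16, gtol=2.3e-16, x_scale='jac')
        return sol.cost, sol.x

    thr = 2.0 * best.cost + 1e-17 * len(loads)

    def edge(direction: float) -> float:
        inside = float(x_best[0])
        outside = None
        for _ in range(40):
            cand = inside * (1.0 + 0.05 * direction)
            if not lb[0] < cand < ub[0]:
                break
            if profile(cand)[0] > thr:
                outside = cand
                break
            inside = cand
        if outside is None:
            return inside
        for _ in range(12):
            mid = 0.5 * (inside + outside)
            if profile(mid)[0] <= thr:
                inside = mid
            else:
                outside = mid
        return inside

    f1_centre = 0.5 * (edge(-1.0) + edge(+1.0))
    cost_c, x_rest = profile(f1_centre)
    fit = SECFit(F1=float(f1_centre), dlSEC1=float(x_rest[0]), k_sh=float(x_rest[1]),
                 k=float(x_rest[2]), l_SEC0=l_SEC0,
                 residual=float(np.sqrt(2 * cost_c / len(loads))),
                 n_points=len(loads))
    if passive_points is None:
        return fit

    # stage B: local joint refinement with the passive sweep, which probes
    # the toe forces absolutely (lever length = l_SEC0 + SEC stretch +
    # PEC slack length + PEC stretch); residuals in force space so the
    # per-point noise is uniform
    pp = np.asarray(passive_points, dtype=float)
    keep = pp[:, 1] > max(3.0 * sd, 1e-6 * f0)
    pas_l, pas_f = pp[keep, 0], pp[keep, 1]
    if len(pas_l) < 3:
        return fit
    try:
        pec0 = fit_passive(pp, fit, f0)
    except EstimationError:
        return fit
    sigma_f = max(sd, 1e-8 * f0)
    sigma_jump = max(0.4 * sd / max(fit.k, 1e-3), 1e-9 * l_SEC0)

    def passive_force(x, l_mtc):
        m = SECFit(F1=x[0], dlSEC1=x[1], k_sh=x[2], k=x[3], l_SEC0=0.0)
        k1, k2, l0 = x[4], x[5], x[6]
        out = np.empty(len(l_mtc))
        for i, l in enumerate(l_mtc):
            span_l = l - l_SEC0 - l0
            if span_l <= 0:
                out[i] = 0.0
                continue
            def h(F):
                return m.elongation(F) + np.log1p(F / k1) / k2 - span_l
            hi = max(2.0 * f0, 10.0)
            out[i] = brentq(h, 0.0, hi, xtol=1e-12) if h(hi) > 0 else hi
        return out

    def resid_joint(x):
        m = SECFit(F1=x[0], dlSEC1=x[1], k_sh=x[2], k=x[3], l_SEC0=0.0)
        r_jump = ((m.elongation(loads) - m.elongation(plateaus)) - jumps) / sigma_jump
        r_pas = (passive_force(x, pas_l) - pas_f) / sigma_f
        return np.concatenate([r_jump, r_pas, [1e3 * stiffening_penalty(x)]])

    lb_j = lb + [1e-12, 1e-4, 1e-3]
    ub_j = ub + [np.inf, 10.0, float(pas_l.max() - l_SEC0)]
    x0 = np.clip([fit.F1, fit.dlSEC1, fit.k_sh, fit.k,
                  max(pec0.k1, 1e-10), pec0.k2, max(pec0.l_PEC0, 1e-3)], lb_j, ub_j)
    try:
        sol = least_squares(resid_joint, x0, bounds=(lb_j, ub_j),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:
        return fit
    return SECFit(F1=float(sol.x[0]), dlSEC1=float(sol.x[1]), k_sh=float(sol.x[2]),
                  k=float(sol.x[3]), l_SEC0=l_SEC0,
                  residual=float(np.sqrt(2 * sol.cost / len(sol.fun))),
                  n_points=len(loads) + len(pas_l))


def _fit_sec_from_release(
    trace: SimulationTrace, l_SEC0: float,
    v_CCmax_bound: float | None, n_iter: int,
) -> SECFit:
    proto: ProtocolSpec = trace.meta.get("protocol")
    if proto is None or proto.ramp_velocity is None:
        raise EstimationError("quick-release trace lacks ramp protocol metadata")
    speed = abs(proto.ramp_velocity)
    v_bound = speed / 2.0 if v_CCmax_bound is None else float(v_CCmax_bound)
    if speed <= v_bound:
        raise EstimationError(
            f"ramp speed {speed:.1f} mm/s does not exceed the CC speed bound {v_bound:.1f} mm/s")

    sd = _noise_sd_estimate(trace)
    noisy = sd > 0.0
    i0 = int(np.searchsorted(trace.t, proto.ramp_start))
    f0 = float(trace.F_total[max(i0 - 1, 0)])
    floor = max(1e-3 * f0, 3.0 * sd)
    rel = np.nonzero(trace.F_total[i0:] <= floor)[0]
    if rel.size == 0:
        raise EstimationError("force never reaches zero during the release")
    i_zero = i0 + int(rel[0])
    sl = slice(i0, i_zero + 1)
    t = trace.t[sl]
    f = np.clip(_maybe_smooth(trace.F_total[sl], noisy, window=15, order=2), 0.0, None)
    l_mtc = trace.l_MTC[sl]
    n = len(t)
    if n < 8:
        raise EstimationError("too few samples within the release")

    c = np.zeros(n)   # fiber displacement relative to the zero-force instant
    fit: SECFit | None = None
    prev = None
    it = 0
    for it in range(1, n_iter + 1):
        dl_sec = (l_mtc - l_mtc[-1]) - c
        fit = _fit_sec_curve(dl_sec, f)
        x = np.array([fit.F1, fit.dlSEC1, fit.k_sh, fit.k])
        if prev is not None and np.all(np.abs(x - prev) <= 1e-10 * np.abs(prev) + 1e-12):
            break
        prev = x
        l_cc = l_mtc - l_SEC0 - fit.elongation(f)
        l_cc = _maybe_smooth(l_cc, noisy)
        v = -np.gradient(l_cc, t)              # shortening speed, mm/s
        v = np.clip(v, 0.0, v_bound)
        disp = np.concatenate([[0.0], np.cumsum(-0.5 * (v[1:] + v[:-1]) * np.diff(t))])
        c = disp - disp[-1]
    fit.l_SEC0 = l_SEC0
    fit.n_iter = it
    fit.n_points = n
    return fit


def _fit_sec_curve(dl: np.ndarray, f: np.ndarray) -> SECFit:
    f_max = float(f.max())
    dl_max = float(dl.max())

    def resid(x):
        f1, dl1, ksh, k = x
        m = SECFit(F1=f1, dlSEC1=dl1, k_sh=ksh, k=k, l_SEC0=0.0)
        return m.force(dl) - f

    order = np.argsort(dl)
    dls, fs = dl[order], f[order]

    def dl_at(frac):
        return float(np.interp(frac * f_max, fs, dls))

    top = fs >= 0.7 * f_max
    k0 = max(np.polyfit(dls[top], fs[top], 1)[0], 1e-3) if top.sum() >= 2 else f_max / max(dl_max, 1e-6)
    starts = []
    for frac, ksh in ((0.31, 2.2), (0.4, 2.7), (0.25, 1.6), (0.5, 3.3), (0.35, 1.0)):
        starts.append([frac * f_max, max(dl_at(frac), 1e-4), ksh, k0])
    best = None
    lb = [1e-9, 1e-6, 1e-3, 1e-6]
    ub = [0.95 * f_max, max(dl_max, 1e-3), 12.0, np.inf]
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise EstimationError("SEC curve fit failed from all starts")
    f1, dl1, ksh, k = best.x
    return SECFit(F1=float(f1), dlSEC1=float(dl1), k_sh=float(ksh), k=float(k),
                  l_SEC0=0.0, residual=float(np.sqrt(2 * best.cost / len(dl))))


# -- stage 2: parallel elasticity ---------------------------------------------

def fit_passive(
    points: np.ndarray, sec: SECFit, f_im_scale: float,
) -> PECFit:
    """Parallel-elastic parameters from the passive length sweep.

    Each passive lever force is carried by the SEC in series with the PEC:
    the CC/PEC length is the lever length minus the SEC rest length and
    the SEC stretch at that force.  An exponential force-elongation law is
    then fitted jointly (scale, exponent and slack length free); the "last
    length with ~zero force" rule (threshold 0.5% of the maximum force)
    only initializes the slack length, since the exponential toe makes it
    a biased point estimate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EstimationError("need >= 5 passive (length, force) points")
    l_mtc, f = pts[:, 0], np.clip(pts[:, 1], 0.0, None)
    thresh = 0.005 * f_im_scale
    if (f > thresh).sum() < 2:
        return PECFit(k1=0.0, k2=1.0, l_PEC0=float(l_mtc.max() - sec.l_SEC0),
                      n_points=len(pts), slack=True)
    l_cc = l_mtc - sec.l_SEC0 - sec.elongation(f)

    below = l_cc[f <= thresh]
    l0_init = float(below.max()) if below.size else float(l_cc.min())

    def resid(x):
        return PECFit(k1=x[0], k2=x[1], l_PEC0=x[2]).force(l_cc) - f

    # the slack length is a physical length: keep it positive even when a
    # noisy toe would prefer to run it negative
    lb = [1e-12, 1e-4, 1e-3]
    ub = [np.inf, 10.0, float(l_cc.max())]
    best = None
    for k2_0 in (0.2, 0.4, 0.7):
        f_top = float(f.max())
        span = max(float(l_cc.max()) - l0_init, 1e-3)
        k1_0 = max(f_top / math.expm1(k2_0 * span), 1e-9)
        x0 = np.clip([k1_0, k2_0, l0_init], lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise EstimationError("PEC fit failed from all starts")
    return PECFit(k1=float(best.x[0]), k2=float(best.x[1]), l_PEC0=float(best.x[2]),
                  residual=float(np.sqrt(2 * best.cost / len(pts))), n_points=len(pts))


# -- stage 3: active force-length ---------------------------------------------

def steady_forces_from_trace(trace: SimulationTrace) -> float:
    """Steady tetanic force: mean over the late stimulated window."""
    proto: ProtocolSpec = trace.meta["protocol"]
    t0, t1 = proto.stimulation_off - 0.15, proto.stimulation_off - 0.01
    mask = (trace.t >= t0) & (trace.t <= t1)
    if mask.sum() < 5:
        raise EstimationError("trace too short for a steady-force window")
    return float(trace.F_total[mask].mean())


def fit_force_length(
    active_points: np.ndarray, sec: SECFit, pec: PECFit,
) -> ForceLengthFit:
    """Active CC force-length relation from the isometric series.

    CC lengths are recovered by inverting the fitted SEC law at the
    measured total force; the PEC contribution at that CC length is
    subtracted to isolate the contractile force.  The piecewise-linear
    relation (two ascending segments, plateau, descending segment) is
    fitted with free breakpoints; the descending limb is flagged
    low-confidence when fewer than 3 points lie beyond the plateau, since
    the passive-force cap truncates the long-length data.
    """
    pts = np.asarray(active_points, dtype=float)
    if len(pts) < 8:
        raise EstimationError("need >= 8 isometric series points")
    l_mtc, f_tot = pts[:, 0], pts[:, 1]
    l_cc = l_mtc - sec.l_SEC0 - sec.elongation(f_tot)
    f_cc = f_tot - pec.force(l_cc)

    i_max = int(np.argmax(f_cc))
    f_im0 = float(f_cc[i_max])
    b_opt0 = float(l_cc[i_max])

    def model(x, l):
        f_im, f_c, b1, d21, d_o2, d3o, d43 = x
        b2 = b1 + d21
        bo = b2 + d_o2
        b3 = bo + d3o
        b4 = b3 + d43
        out = np.zeros_like(l)
        out = np.where((l >= b1) & (l <= b2), f_c * (l - b1) / d21, out)
        out = np.where((l > b2) & (l <= bo), f_c + (1 - f_c) * (l - b2) / d_o2, out)
        out = np.where((l > bo) & (l <= b3), 1.0, out)
        out = np.where((l > b3) & (l <= b4), (b4 - l) / d43, out)
        return f_im * out

    def resid(x):
        return model(x, l_cc) - f_cc

    lb = [0.3 * f_im0, 0.05, 0.05 * b_opt0, 1e-3, 1e-3, 1e-3, 1e-3]
    ub = [3.0 * f_im0, 0.995, b_opt0, b_opt0, b_opt0, b_opt0, 3.0 * b_opt0]
    best = None
    for (r1, r2, r3, r4, fc0) in (
        (0.45, 0.85, 1.12, 2.0, 0.85), (0.5, 0.8, 1.2, 1.8, 0.75),
        (0.4, 0.9, 1.1, 2.2, 0.9), (0.55, 0.82, 1.15, 2.4, 0.8),
    ):
        x0 = [f_im0, fc0, r1 * b_opt0, (r2 - r1) * b_opt0, (1 - r2) * b_opt0,
              (r3 - 1) * b_opt0, (r4 - r3) * b_opt0]
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise EstimationError("force-length fit failed from all starts")
    f_im, f_c, b1, d21, d_o2, d3o, d43 = best.x
    b2, bo = b1 + d21, b1 + d21 + d_o2
    b3, b4 = bo + d3o, bo + d3o + d43
    n_desc = int(np.sum(l_cc > b3))
    return ForceLengthFit(
        F_im=float(f_im), l_CCopt=float(bo),
        l1=float(b1 / bo), l2=float(b2 / bo), l3=float(b3 / bo), l4=float(b4 / bo),
        f_c=float(f_c), residual=float(np.sqrt(2 * best.cost / len(pts))),
        n_points=len(pts), n_descending=n_desc,
        low_confidence_descending=n_desc < 3)


# -- stage 4: force-velocity --------------------------------------------------

def fit_hill_hyperbola(v_norm: np.ndarray, phi: np.ndarray) -> ForceVelocityFit:
    """Least-squares Hill hyperbola through (shortening speed, force) pairs.

    Speeds in l_CCopt/s, forces as fractions of the isometric maximum.
    """
    v = np.asarray(v_norm, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if len(v) < 4:
        raise EstimationError("need >= 4 force-velocity pairs")

    def resid(x):
        vmax, curv = x
        return (vmax - v) / (vmax + v / curv) - phi

    lb = [float(v.max()) * 1.0001, 0.01]
    ub = [float(v.max()) * 50.0, 10.0]
    best = None
    for x0 in ([1.15 * v.max(), 0.3], [1.5 * v.max(), 0.8], [1.05 * v.max(), 0.12]):
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise EstimationError("Hill hyperbola fit failed")
    return ForceVelocityFit(v_CCmax=float(best.x[0]), curv=float(best.x[1]),
                            residual=float(np.sqrt(2 * best.cost / len(v))),
                            n_pairs=len(v))


def fit_force_velocity(
    trials: Sequence[SimulationTrace], sec: SECFit, pec: PECFit, fl: ForceLengthFit,
    plateau_tol: float = 0.01, plateau_min_duration: float = 0.05,
) -> ForceVelocityFit:
    """Hill force-velocity relation from after-loaded isotonic releases.

    In each usable trial the force clamp defines a constant-force plateau
    (within 1% of the afterload for at least 50 ms).  During the plateau
    the shortening speed is read from the lever, CC lengths are recovered
    through the fitted SEC inverse, and each sample yields a normalized
    (force, velocity) pair after correcting for the force-length factor
    and the PEC force at the instantaneous CC length; activation is
    saturated because the release happens well after the tetanic rise.
    All pairs are pooled into one hyperbola fit.
    """
    v_all, phi_all = [], []
    used, excluded = 0, []
    for trace in trials:
        proto: ProtocolSpec = trace.meta.get("protocol")
        if proto is None or proto.afterload is None:
            excluded.append((trace.meta.get("muscle", "?"), "no afterload metadata"))
            continue
        load = proto.afterload
        sd = _noise_sd_estimate(trace)
        noisy = sd > 0.0
        tol = max(plateau_tol * load, 3.0 * sd)
        t_rel = proto.release_time
        if t_rel is None:
            after_on = trace.t >= proto.stimulation_on
            hit = np.nonzero(after_on & (trace.F_total >= load - tol))[0]
            if hit.size == 0:
                excluded.append((proto.label, "afterload never reached"))
                continue
            t_rel = float(trace.t[hit[0]])
        in_clamp = (trace.t >= t_rel) & (np.abs(trace.F_total - load) <= tol)
        idx = np.nonzero(in_clamp)[0]
        if idx.size == 0:
            excluded.append((proto.label, "no plateau samples"))
            continue
        # longest contiguous run
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, breaks + 1)
        run = max(runs, key=len)
        dt = float(np.median(np.diff(trace.t)))
        if len(run) * dt < plateau_min_duration:
            excluded.append((proto.label, "plateau shorter than detector window"))
            continue
        run = run[run >= run[0] + max(1, int(0.005 / dt))]  # skip the release instant
        t = trace.t[run]
        f = _maybe_smooth(trace.F_total[run], noisy, window=21, order=2)
        l_cc = trace.l_MTC[run] - sec.l_SEC0 - sec.elongation(f)
        l_cc = _maybe_smooth(l_cc, noisy)
        v_mm = -np.gradient(l_cc, t)
        fl_val = fl.factor(l_cc / fl.l_CCopt)
        phi = (f - pec.force(l_cc)) / (fl.F_im * np.where(fl_val > 0, fl_val, np.nan))
        ok = (fl_val >= 0.2) & (phi > 0.02) & (phi < 0.98) & (v_mm > 0)
        if ok.sum() < 3:
            excluded.append((proto.label, "no valid plateau samples after correction"))
            continue
        v_all.append(v_mm[ok] / fl.l_CCopt)
        phi_all.append(phi[ok])
        used += 1
    if used < 4:
        raise EstimationError(
            f"only {used} usable isotonic trials (need >= 4); excluded: {excluded}")
    fit = fit_hill_hyperbola(np.concatenate(v_all), np.concatenate(phi_all))
    fit.n_trials_used = used
    fit.trials_excluded = excluded
    return fit


# -- stage 5: activation ------------------------------------------------------

def fit_activation_tau(
    trace: SimulationTrace, sec: SECFit, pec: PECFit,
    fl: ForceLengthFit, fv: ForceVelocityFit,
) -> tuple[float, float, bool]:
    """Activation time constant from the tetanic force rise at optimum.

    The activation required at each sample is obtained by inverting the
    model chain (SEC stretch -> CC length -> CC speed -> force-velocity
    factor) and fitted with the first-order rise 1 - exp(-t/tau).
    Returns (tau, rms residual, below_resolution flag).
    """
    proto: ProtocolSpec = trace.meta["protocol"]
    sd = _noise_sd_estimate(trace)
    noisy = sd > 0.0
    f = _maybe_smooth(trace.F_total, noisy, window=21, order=3)
    plateau = steady_forces_from_trace(trace)
    rise = (trace.t >= proto.stimulation_on) & (f >= 0.03 * plateau) & (f <= 0.97 * plateau) \
        & (trace.t <= proto.stimulation_off)
    idx = np.nonzero(rise)[0]
    if idx.size < 6:
        raise EstimationError("tetanus trace has no resolvable force rise")
    t = trace.t[idx]
    l_cc = trace.l_MTC[idx] - sec.l_SEC0 - sec.elongation(f[idx])
    l_cc = _maybe_smooth(l_cc, noisy)
    v_norm = np.clip(-np.gradient(l_cc, t) / fl.l_CCopt, 0.0, fv.v_CCmax * 0.999)
    a_req = (f[idx] - pec.force(l_cc)) / (fl.F_im * fl.factor(l_cc / fl.l_CCopt) * fv.factor(v_norm))
    ok = np.isfinite(a_req) & (a_req > 0.01) & (a_req < 0.995)
    if ok.sum() < 6:
        raise EstimationError("too few valid activation samples")
    tt, aa = t[ok] - proto.stimulation_on, a_req[ok]

    def rise_model(x, tau):
        return 1.0 - np.exp(-x / tau)

    tau0 = max(float(np.median(-tt / np.log(np.clip(1 - aa, 1e-12, 1)))), 1e-4)
    popt, _ = curve_fit(rise_model, tt, aa, p0=[tau0], bounds=(1e-6, 10.0),
                        xtol=1e-15, ftol=1e-15)
    tau = float(popt[0])
    res = float(np.sqrt(np.mean((rise_model(tt, tau) - aa) ** 2)))
    dt = float(np.median(np.diff(trace.t)))
    return tau, res, tau < 2 * dt


# -- full pipeline ------------------------------------------------------------

def estimate_all(expset: ExperimentSet) -> EstimationReport:
    """Run all stages in dependency order and assemble a parameter record.

    Stage failures are recorded in ``stage_errors`` and the report is
    still emitted with whatever could be fitted.  With ground truth in the
    set, per-parameter recovery errors (%) are attached.
    """
    report = EstimationReport(muscle=expset.muscle, params=None,
                              seed=expset.seed, noise=expset.noise)
    anatomy = expset.anatomy
    if "l_SEC0" not in anatomy:
        raise EstimationError("experiment set lacks the anatomical l_SEC0 anchor")
    l_sec0 = float(anatomy["l_SEC0"])

    sec = pec = fl = fv = None
    try:
        sec = fit_sec(
            expset.trace(expset.quick_release_key), l_sec0,
            isotonic_trials=[expset.trace(k) for k in expset.isotonic_keys],
            passive_points=expset.passive_points)
        report.sec = sec
    except Exception as exc:
        report.stage_errors["sec"] = str(exc)
    f_scale = max(
        (steady_forces_from_trace(expset.trace(k)) for k in expset.isometric_keys),
        default=1.0)
    if sec is not None:
        try:
            pec = fit_passive(expset.passive_points, sec, f_scale)
            report.pec = pec
        except Exception as exc:
            report.stage_errors["passive"] = str(exc)
    if sec is not None and pec is not None:
        try:
            active = np.array([
                [expset.trace(k).meta["protocol"].l_MTC_start,
                 steady_forces_from_trace(expset.trace(k))]
                for k in expset.isometric_keys])
            fl = fit_force_length(active, sec, pec)
            report.force_length = fl
        except Exception as exc:
            report.stage_errors["force_length"] = str(exc)
    if fl is not None:
        try:
            fv = fit_force_velocity(
                [expset.trace(k) for k in expset.isotonic_keys], sec, pec, fl)
            report.force_velocity = fv
        except Exception as exc:
            report.stage_errors["force_velocity"] = str(exc)
    if fl is not None and fv is not None and expset.tetanus_key:
        try:
            tau, res, below = fit_activation_tau(
                expset.trace(expset.tetanus_key), sec, pec, fl, fv)
            report.tau = tau
            report.tau_residual = res
            if below:
                report.stage_errors["tau_flag"] = "tau below sampling resolution"
        except Exception as exc:
            report.stage_errors["tau"] = str(exc)

    if all(x is not None for x in (sec, pec, fl, fv)) and report.tau is not None:
        try:
            report.params = MuscleParameters(
                name=expset.muscle,
                F_im=fl.F_im, l_CCopt=fl.l_CCopt,
                l1=fl.l1, l2=fl.l2, l3=fl.l3, l4=fl.l4, f_c=fl.f_c,
                v_CCmax=fv.v_CCmax, curv=fv.curv, tau=report.tau,
                F1_frac=sec.F1 / fl.F_im, dlSEC1_frac=sec.dlSEC1 / sec.l_SEC0,
                k_sh=sec.k_sh, k=sec.k, l_SEC0=sec.l_SEC0,
                k1=pec.k1, k2=pec.k2, l_PEC0=pec.l_PEC0,
                mass=float(anatomy.get("mass", 1.0)),
                density=float(anatomy.get("density", 1.056)),
                L_MTC_0=float(anatomy.get("L_MTC_0", l_sec0)),
                l_fm=anatomy.get("l_fm"))
        except Exception as exc:
            report.stage_errors["assembly"] = str(exc)

    if report.params is not None and expset.truth is not None:
        errors = {}
        for fld in dc_fields(MuscleParameters):
            true = getattr(expset.truth, fld.name)
            fitted = getattr(report.params, fld.name)
            if isinstance(true, (int, float)) and isinstance(fitted, (int, float)) and true:
                errors[fld.name] = 100.0 * (fitted - true) / true
        report.recovery_errors_pct = errors
    return report


# -- effect size --------------------------------------------------------------

class EffectSize(NamedTuple):
    f: float
    label: str


def effect_size(group_means: Sequence[float], within_sd: float) -> EffectSize:
    """Cohen's f: population SD of the group means over the within-group SD.

    Classified as small/medium/large at 0.1/0.25/0.40.
    """
    means = np.asarray(list(group_means), dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 group means")
    if not within_sd > 0:
        raise ValueError("within-population SD must be > 0")
    f = float(np.std(means, ddof=0) / within_sd)
    if f >= 0.40:
        label = "large"
    elif f >= 0.25:
        label = "medium"
    elif f >= 0.10:
        label = "small"
    else:
        label = "negligible"
    return EffectSize(f=f, label=label)
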