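"""Force depression and force enhancement from isokinetic ramp pairs.

After active shortening, steady isometric force is depressed relative to
a purely isometric reference contraction at the same final length (force
depression, FD); after active stretch it is enhanced (force enhancement,
FE).  Both are quantified as the force difference between the ramp
experiment and its isometric reference, read a fixed delay after the ramp
end (500 ms; 1300 ms for the slow soleus) and expressed in % of the
maximum isometric force.  This module measures the effect from trace
pairs; it contains no mechanistic model of it — a pure Hill-type model
produces none, which the quantifier makes explicit.

The measured in-situ reference values (FD and FE per ramp velocity and
muscle, in % F_im) are packaged in :data:`REFERENCE_HISTORY` for
comparison output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contraction_simulator import ProtocolSpec, SimulationTrace
from .synthetic_experiments import ExperimentSet

__all__ = [
    "HistoryResult",
    "quantify_history",
    "history_table",
    "eval_delay_for",
    "fd_decreases_with_velocity",
    "REFERENCE_HISTORY",
]

#: measured rabbit calf values, % F_im (mean, SD) keyed
#: [muscle][effect][ramp velocity in l_fm/s]; experimental reference data,
#: not a simulation target
REFERENCE_HISTORY: dict = {
    "GAS": {
        "FD": {0.35: (17.3, 0.9), 0.7: (16.6, 0.7), 1.4: (16.0, 0.7)},
        "FE": {0.35: (7.7, 1.6), 0.7: (7.7, 1.4), 1.4: (7.7, 1.6)},
    },
    "PLA": {
        "FD": {0.35: (17.8, 4.8), 0.7: (15.4, 4.0), 1.4: (14.6, 3.9)},
        "FE": {0.35: (17.1, 9.6), 0.7: (17.0, 9.8), 1.4: (17.0, 8.7)},
    },
    "SOL": {
        "FD": {0.35: (9.7, 1.2), 0.7: (8.0, 0.9), 1.4: (5.8, 1.5)},
        "FE": {0.35: (11.3, 1.5), 0.7: (11.3, 1.7), 1.4: (11.2, 1.3)},
    },
}


@dataclass(frozen=True)
class HistoryResult:
    muscle: str
    velocity: float          # l_fm/s (or mm/s for the fallback protocol)
    direction: str           # "shortening" | "lengthening"
    effect: str              # "FD" | "FE"
    eval_delay: float        # s after ramp end
    value_pct_fim: float     # positive magnitude, % F_im
    signed_difference_n: float   # reference - ramp (FD) / ramp - reference (FE)
    ramp_key: str = ""
    reference_key: str = ""


def eval_delay_for(muscle: str) -> float:
    """Per-muscle evaluation delay after the ramp end (s)."""
    return 1.3 if muscle.upper() == "SOL" else 0.5


def _force_at(trace: SimulationTrace, t_eval: float, window: float | None) -> float:
    if t_eval > trace.t[-1] + 1e-9:
        raise ValueError(f"trace ends at {trace.t[-1]:.3f} s, before evaluation time {t_eval:.3f} s")
    if window is None:
        i = int(np.argmin(np.abs(trace.t - t_eval)))
        return float(trace.F_total[i])
    mask = (trace.t >= t_eval - window / 2) & (trace.t <= t_eval + window / 2)
    if not mask.any():
        raise ValueError("averaging window contains no samples")
    return float(trace.F_total[mask].mean())


def quantify_history(
    ramp_trace: SimulationTrace,
    reference_trace: SimulationTrace,
    f_im: float,
    eval_delay: float,
    window: float | None = None,
    length_tol: float = 0.1,
) -> HistoryResult:
    """FD or FE from one ramp/reference pair, in % F_im.

    The two traces must share the target length (checked to ``length_tol``
    mm).  The force difference is read at the single sample nearest
    (ramp end + eval_delay); pass ``window`` (s) for a short mean instead.
    FD (after shortening) is reference minus ramp, FE (after lengthening)
    is ramp minus reference; ``value_pct_fim`` is the positive magnitude
    with the direction kept separately.
    """
    proto: ProtocolSpec = ramp_trace.meta["protocol"]
    if proto.ramp_velocity is None:
        raise ValueError("first trace is not a ramp experiment")
    direction = "lengthening" if proto.ramp_velocity > 0 else "shortening"
    effect = "FE" if direction == "lengthening" else "FD"
    t_eval = proto.ramp_end + eval_delay

    target = proto.l_mtc_of_t(proto.ramp_end)
    i_ref = int(np.argmin(np.abs(reference_trace.t - t_eval)))
    ref_len = float(reference_trace.l_MTC[i_ref])
    if abs(ref_len - target) > length_tol:
        raise ValueError(
            f"target-length mismatch: ramp ends at {target:.2f} mm, "
            f"reference holds {ref_len:.2f} mm (tolerance {length_tol} mm)")

    f_ramp = _force_at(ramp_trace, t_eval, window)
    f_ref = _force_at(reference_trace, t_eval, window)
    signed = (f_ref - f_ramp) if effect == "FD" else (f_ramp - f_ref)
    velocity = abs(proto.ramp_velocity)
    meta_v = ramp_trace.meta.get("velocity_lfm")
    return HistoryResult(
        muscle=ramp_trace.meta.get("muscle", ""),
        velocity=float(meta_v) if meta_v is not None else velocity,
        direction=direction, effect=effect, eval_delay=eval_delay,
        value_pct_fim=abs(signed) / f_im * 100.0,
        signed_difference_n=signed,
        ramp_key=proto.label)


def history_table(
    expset: ExperimentSet, f_im: float,
    eval_delay: float | None = None, window: float | None = None,
    include_reference: bool = True,
) -> pd.DataFrame:
    """FD/FE table over all ramp/reference pairs of a history set.

    One row per (velocity, direction); columns hold the computed value and,
    when available, the measured in-situ mean and SD for the same muscle
    and velocity.  Missing pairs are reported with a flag instead of
    aborting.
    """
    delay = eval_delay_for(expset.muscle) if eval_delay is None else eval_delay
    rows = []
    for (vel, direction), (ramp_key, ref_key) in sorted(expset.history_groups.items()):
        row = {"muscle": expset.muscle, "velocity_lfm_s": vel, "direction": direction,
               "effect": "FD" if direction == "shortening" else "FE",
               "eval_delay_s": delay, "value_pct_fim": np.nan, "flag": ""}
        try:
            ramp = expset.trace(ramp_key)
            ramp.meta.setdefault("velocity_lfm", vel)
            res = quantify_history(ramp, expset.trace(ref_key), f_im, delay, window=window)
            row["value_pct_fim"] = res.value_pct_fim
            row["signed_difference_n"] = res.signed_difference_n
        except (KeyError, ValueError) as exc:
            row["flag"] = str(exc)
        if include_reference:
            ref = REFERENCE_HISTORY.get(expset.muscle.upper(), {})
            mean_sd = ref.get(row["effect"], {}).get(vel)
            row["measured_pct_fim"] = mean_sd[0] if mean_sd else np.nan
            row["measured_sd"] = mean_sd[1] if mean_sd else np.nan
        rows.append(row)
    if not rows:
        raise ValueError("experiment set contains no history ramp pairs")
    return pd.DataFrame(rows)


def fd_decreases_with_velocity(table: pd.DataFrame, column: str = "value_pct_fim") -> bool:
    """True when force depression falls monotonically with ramp velocity."""
    fd = table[table["effect"] == "FD"].sort_values("velocity_lfm_s")
    vals = fd[column].to_numpy(dtype=float)
    if len(vals) < 2 or np.any(np.isnan(vals)):
        raise ValueError("need FD values at >= 2 velocities")
    return bool(np.all(np.diff(vals) < 0))
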