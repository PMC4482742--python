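"""Synthetic in-situ experiments and digitized muscle architectures.

This module stands in for the in-situ recordings and for the manual 3D
digitization: it drives the forward simulator through the same protocol
families used on the rabbit calf muscles (isometric length series,
after-loaded isotonic releases, a fast isokinetic release for the series
elasticity, tetanic rises, isokinetic ramp/reference pairs for history
effects) and emulates digitized fascicle bundles as noisy 20-point
polylines.  Ground truth is stored alongside the data so estimation
pipelines can be scored.

All randomness flows through one seeded generator; regenerating with the
same seed is bit-identical.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .muscle_model import MuscleParameters, load_parameters, save_parameters, pec_force, sec_elongation
from .contraction_simulator import (
    ProtocolSpec,
    SimulationTrace,
    optimal_mtc_length,
    passive_force_at_length,
    simulate,
)
from .architecture3d import Fascicle, FascicleSet

__all__ = [
    "NoiseModel",
    "ExperimentSet",
    "generate_experiment_set",
    "generate_clean_experiment_set",
    "generate_history_set",
    "generate_fascicle_set",
    "apply_noise",
    "inject_plateau_offset",
    "save_experiment_set",
    "load_experiment_set",
    "series_lengths",
]

HISTORY_VELOCITIES = (0.35, 0.7, 1.4)   # l_fm/s, the in-situ ramp speeds
RAMP_EXCURSION_LFM = 0.3                # ramp length [l_fm]
RAMP_START_OFFSET_LFM = 0.15            # ramps start at optimum +/- 0.15 l_fm
PASSIVE_CAP_FRAC = 0.2                  # series truncated at 0.2 F_im passive
PRECONTRACTION = 0.3                    # s, isometric pre-contraction before ramps


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the synthetic recordings.

    Force noise is additive Gaussian on the sampled force channel with SD
    ``force_sd_frac * F_im`` (default 0.5% — the recordings' noise spectrum
    was not characterized, so the simplest defensible model is used).
    ``digitizer_sd`` is the per-coordinate jitter of the manual 3D
    digitizer (0.07 mm accuracy).
    """

    force_sd_frac: float = 0.005   # [F_im]
    length_sd: float = 0.0         # mm, on the lever-position channel
    digitizer_sd: float = 0.07     # mm, per coordinate of digitized points
    sample_rate: float = 1000.0    # Hz

    def __post_init__(self) -> None:
        if min(self.force_sd_frac, self.length_sd, self.digitizer_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(force_sd_frac=0.0, length_sd=0.0, digitizer_sd=0.0)


@dataclass
class ExperimentSet:
    """One muscle's collection of synthetic recordings plus ground truth."""

    muscle: str
    truth: MuscleParameters | None
    traces: dict[str, SimulationTrace]
    isometric_keys: list[str] = field(default_factory=list)
    passive_points: np.ndarray | None = None   # (n, 2): l_MTC [mm], F [N]
    isotonic_keys: list[str] = field(default_factory=list)
    quick_release_key: str | None = None
    tetanus_key: str | None = None
    history_groups: dict = field(default_factory=dict)  # (vel, dir) -> (ramp, ref)
    anatomy: dict = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel.zero)
    seed: int | None = None

    def trace(self, key: str) -> SimulationTrace:
        return self.traces[key]


# -- protocol construction ----------------------------------------------------

def series_lengths(p: MuscleParameters) -> list[float]:
    """MTC lengths of the isometric series.

    Coarse 2 mm steps from just below the active range (CC at 0.9*l1) up to
    4 mm under the optimum, fine 1 mm steps across the plateau region, and
    a final contraction exactly at the passive-force cap (the muscles were
    lengthened until passive force reached about 0.2 F_im).  Increments
    stay within the 1-2 mm used in situ.
    """
    l_opt = optimal_mtc_length(p)
    start = p.l_SEC0 + 0.9 * p.l1 * p.l_CCopt
    # passive-cap length by bisection on the passive equilibrium
    lo, hi = l_opt, l_opt + 3.0 * p.l_CCopt
    cap = PASSIVE_CAP_FRAC * p.F_im
    while passive_force_at_length(hi, p) < cap:
        hi += p.l_CCopt
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if passive_force_at_length(mid, p) < cap:
            lo = mid
        else:
            hi = mid
    l_cap = 0.5 * (lo + hi)

    split = l_opt - 4.0
    if l_cap <= split + 2.0 or split <= start + 2.0:
        return [float(x) for x in np.linspace(start, l_cap, 18)]
    b_span = split - start
    t_span = l_cap - split
    n_b = int(np.clip(round(b_span / 1.5), math.ceil(b_span / 2.0), math.floor(b_span)))
    m = int(np.clip(round(t_span / 1.1), math.ceil(t_span / 2.0), math.floor(t_span)))
    while n_b + m + 1 < 15 and m < math.floor(t_span):
        m += 1
    while n_b + m + 1 < 15 and n_b < math.floor(b_span):
        n_b += 1
    while n_b + m + 1 > 20 and n_b > math.ceil(b_span / 2.0):
        n_b -= 1
    bottom = np.linspace(start, split, n_b, endpoint=False)
    top = np.linspace(split, l_cap, m + 1)
    return [float(x) for x in np.concatenate([bottom, top])]


def _isometric_protocol(l_mtc: float, sample_rate: float, label: str) -> ProtocolSpec:
    return ProtocolSpec(mode="isometric", l_MTC_start=l_mtc,
                        stimulation_on=0.1, stimulation_off=0.9,
                        total_duration=0.95, sample_rate=sample_rate, label=label)


def _isotonic_protocol(l_mtc: float, load: float, sample_rate: float, label: str) -> ProtocolSpec:
    return ProtocolSpec(mode="isotonic_afterload", l_MTC_start=l_mtc,
                        stimulation_on=0.05, stimulation_off=0.75,
                        release_time=0.45, afterload=load,
                        total_duration=0.78, sample_rate=sample_rate, label=label)


def _quick_release_protocol(p: MuscleParameters, sample_rate: float) -> ProtocolSpec:
    l_opt = optimal_mtc_length(p)
    f_plateau = p.F_im + pec_force(p.l_CCopt - p.l_PEC0, p)
    ramp_len = 2.0 * sec_elongation(f_plateau, p) + 0.2 * p.l_CCopt
    speed = 2.0 * p.v_CCmax * p.l_CCopt  # mm/s, exceeds the CC speed limit
    return ProtocolSpec(mode="quick_release", l_MTC_start=l_opt,
                        stimulation_on=0.05, stimulation_off=0.55,
                        ramp_start=0.45, ramp_velocity=-speed, ramp_length=ramp_len,
                        total_duration=0.6, sample_rate=sample_rate,
                        label="quick_release")


def _anatomy(p: MuscleParameters) -> dict:
    # quantities measured outside the contraction recordings (micrometer,
    # scale, digitization); the series-elastic rest length anchors the
    # absolute CC/SEC length split, which traces alone cannot identify
    a = {"l_SEC0": p.l_SEC0, "mass": p.mass, "density": p.density,
         "L_MTC_0": p.L_MTC_0}
    if p.l_fm is not None:
        a["l_fm"] = p.l_fm
    return a


# -- main generators ----------------------------------------------------------

_CLEAN_CACHE: dict[MuscleParameters, "ExperimentSet"] = {}


def generate_clean_experiment_set(p: MuscleParameters, sample_rate: float = 1000.0) -> ExperimentSet:
    """Noise-free experiment set (deterministic; memoized per parameter record)."""
    if p in _CLEAN_CACHE:
        return _CLEAN_CACHE[p]
    traces: dict[str, SimulationTrace] = {}
    iso_keys: list[str] = []
    lengths = series_lengths(p)
    passive = []
    for i, l_mtc in enumerate(lengths):
        key = f"isometric_{i:02d}"
        traces[key] = simulate(_isometric_protocol(l_mtc, sample_rate, key), p)
        iso_keys.append(key)
        passive.append((l_mtc, passive_force_at_length(l_mtc, p)))

    l_opt = optimal_mtc_length(p)
    iso_loads = np.linspace(0.1, 0.9, 10) * p.F_im
    isotonic_keys = []
    for j, load in enumerate(iso_loads):
        key = f"isotonic_{j:02d}"
        traces[key] = simulate(_isotonic_protocol(l_opt, float(load), sample_rate, key), p)
        isotonic_keys.append(key)

    qr_key = "quick_release"
    traces[qr_key] = simulate(_quick_release_protocol(p, sample_rate), p)

    tet_key = "tetanus"
    traces[tet_key] = simulate(_isometric_protocol(l_opt, sample_rate, tet_key), p)

    out = ExperimentSet(
        muscle=p.name, truth=p, traces=traces, isometric_keys=iso_keys,
        passive_points=np.array(passive), isotonic_keys=isotonic_keys,
        quick_release_key=qr_key, tetanus_key=tet_key,
        anatomy=_anatomy(p), noise=NoiseModel.zero(), seed=None)
    if len(_CLEAN_CACHE) < 16:
        _CLEAN_CACHE[p] = out
    return out


def apply_noise(clean: ExperimentSet, noise: NoiseModel, seed: int) -> ExperimentSet:
    """Fresh noisy realization of a clean experiment set (clean is not modified)."""
    rng = np.random.default_rng(seed)
    f_im = clean.truth.F_im if clean.truth is not None else 1.0
    f_sd = noise.force_sd_frac * f_im
    traces = {}
    for key in sorted(clean.traces):
        tr = clean.traces[key].copy()
        if f_sd > 0:
            tr.F_total = tr.F_total + rng.normal(0.0, f_sd, size=len(tr))
        if noise.length_sd > 0:
            tr.l_MTC = tr.l_MTC + rng.normal(0.0, noise.length_sd, size=len(tr))
        traces[key] = tr
    passive = None
    if clean.passive_points is not None:
        passive = clean.passive_points.copy()
        if f_sd > 0:
            passive[:, 1] = passive[:, 1] + rng.normal(0.0, f_sd, size=len(passive))
    return ExperimentSet(
        muscle=clean.muscle, truth=clean.truth, traces=traces,
        isometric_keys=list(clean.isometric_keys), passive_points=passive,
        isotonic_keys=list(clean.isotonic_keys),
        quick_release_key=clean.quick_release_key, tetanus_key=clean.tetanus_key,
        history_groups=dict(clean.history_groups),
        anatomy=dict(clean.anatomy), noise=noise, seed=seed)


def generate_experiment_set(
    p: MuscleParameters, noise: NoiseModel | None = None, seed: int = 0,
) -> ExperimentSet:
    """Full synthetic parameter-determination data set for one muscle.

    Contains the isometric length series (passive sweep included), ten
    after-loaded isotonic releases at 0.1-0.9 F_im, one fast isokinetic
    release exceeding the CC speed limit, and one tetanic rise at the
    optimum.  Noise is applied after simulation; with zero noise SDs the
    traces equal the raw simulator output.
    """
    noise = noise or NoiseModel()
    clean = generate_clean_experiment_set(p, sample_rate=noise.sample_rate)
    if noise.force_sd_frac == 0.0 and noise.length_sd == 0.0:
        out = apply_noise(clean, noise, seed)  # deep copy, records seed
        return out
    return apply_noise(clean, noise, seed)


def generate_history_set(
    p: MuscleParameters,
    velocities: tuple[float, ...] = HISTORY_VELOCITIES,
    seed: int = 0,
    noise: NoiseModel | None = None,
    sample_rate: float = 1000.0,
) -> ExperimentSet:
    """Isokinetic ramp / isometric reference pairs for history effects.

    For each ramp velocity (in l_fm/s) a shortening and a lengthening ramp
    of 0.3 l_fm is produced, starting at the optimum length +0.15 l_fm and
    -0.15 l_fm respectively, after a 300 ms isometric pre-contraction;
    stimulation continues 500 ms past the ramp end (1300 ms for the slow,
    fatigue-resistant SOL).  Each ramp is paired with an isometric
    reference contraction of the same duration at the target length.
    """
    if p.l_fm is None:
        raise ValueError(f"{p.name}: mean fascicle length l_fm required for history ramps")
    noise = noise or NoiseModel.zero()
    post = 1.3 if p.name.upper() == "SOL" else 0.5
    l_opt = optimal_mtc_length(p)
    excursion = RAMP_EXCURSION_LFM * p.l_fm
    offset = RAMP_START_OFFSET_LFM * p.l_fm

    traces: dict[str, SimulationTrace] = {}
    groups: dict = {}
    for v in velocities:
        speed = v * p.l_fm  # mm/s
        ramp_dur = excursion / speed
        stim_on = 0.1
        ramp_start = stim_on + PRECONTRACTION
        ramp_end = ramp_start + ramp_dur
        stim_off = ramp_end + post + 0.05
        total = stim_off + 0.02
        for direction, sign in (("shortening", -1.0), ("lengthening", +1.0)):
            start = l_opt - sign * offset
            ramp_key = f"ramp_{direction}_{v:g}"
            proto = ProtocolSpec(
                mode="isokinetic_ramp", l_MTC_start=start,
                stimulation_on=stim_on, stimulation_off=stim_off,
                ramp_start=ramp_start, ramp_velocity=sign * speed,
                ramp_length=excursion, total_duration=total,
                sample_rate=sample_rate, label=ramp_key)
            traces[ramp_key] = simulate(proto, p)
            ref_key = f"ref_{direction}_{v:g}"
            ref_proto = ProtocolSpec(
                mode="isometric", l_MTC_start=start + sign * excursion,
                stimulation_on=stim_on, stimulation_off=stim_off,
                total_duration=total, sample_rate=sample_rate, label=ref_key)
            traces[ref_key] = simulate(ref_proto, p)
            groups[(v, direction)] = (ramp_key, ref_key)

    out = ExperimentSet(
        muscle=p.name, truth=p, traces=traces, history_groups=groups,
        anatomy=_anatomy(p), noise=NoiseModel.zero(), seed=seed)
    if noise.force_sd_frac > 0 or noise.length_sd > 0:
        out = apply_noise(out, noise, seed)
    return out


def inject_plateau_offset(trace: SimulationTrace, offset_n: float) -> SimulationTrace:
    """Copy of a ramp trace with a constant force offset after the ramp end.

    Constructs traces with a known history effect so the quantifier can be
    checked against exact ground truth.
    """
    proto: ProtocolSpec = trace.meta["protocol"]
    out = trace.copy()
    out.F_total = out.F_total + np.where(out.t >= proto.ramp_end, offset_n, 0.0)
    out.meta["injected_offset_N"] = offset_n
    return out


# -- digitized architecture ---------------------------------------------------

def generate_fascicle_set(
    template: str = "unipennate",
    n_fascicles: int = 100,
    mean_length: float = 15.0,
    length_sd: float = 2.5,
    mean_pennation: float = 14.0,
    pennation_sd: float = 5.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sagitta_frac: float = 0.02,
    muscle: str = "synthetic",
) -> FascicleSet:
    """Synthetic digitized fascicle bundle as 20-point 3D polylines.

    The line of action runs along +z from the origin landmark to the
    insertion.  Fascicles attach over a proximal sheet and run at their
    (normally distributed) pennation angle to the axis, with a small
    circular-arc bow (midpoint sagitta ``sagitta_frac`` of the length) so
    that arc- and chord-length conventions differ measurably.  Each point
    of every polyline is jittered with the digitizer SD; with all SDs zero
    the geometry is exact (computed pennation equals the drawn angle, the
    chord length equals the drawn length).
    """
    if n_fascicles < 1:
        raise ValueError("n_fascicles must be >= 1")
    if template not in ("unipennate", "bipennate"):
        raise ValueError(f"unknown template {template!r}")
    if mean_length <= 0 or length_sd < 0 or pennation_sd < 0:
        raise ValueError("degenerate length/pennation template parameters")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    axis = np.array([0.0, 0.0, 1.0])
    belly_len = 2.5 * mean_length
    origin = np.array([0.0, 0.0, -0.2 * belly_len])
    insertion = np.array([0.0, 0.0, 1.2 * belly_len])

    lengths = rng.normal(mean_length, length_sd, n_fascicles)
    lengths = np.clip(lengths, 0.1 * mean_length, None)
    angles = np.deg2rad(np.clip(rng.normal(mean_pennation, pennation_sd, n_fascicles), 0.0, 89.0))
    z_attach = rng.uniform(0.0, belly_len, n_fascicles)
    x_attach = rng.uniform(-0.2 * belly_len, 0.2 * belly_len, n_fascicles)
    side = np.ones(n_fascicles)
    if template == "bipennate":
        side[rng.random(n_fascicles) < 0.5] = -1.0

    s = np.linspace(0.0, 1.0, 20)
    fascicles = []
    for i in range(n_fascicles):
        a, L = angles[i], lengths[i]
        # fascicle direction: tilted off the axis in the (y, z) plane,
        # mirrored across the axis for the second head of a bipennate belly
        d = np.array([0.0, side[i] * np.sin(a), np.cos(a)])
        p0 = np.array([x_attach[i], -side[i] * 0.05 * belly_len, z_attach[i]])
        chord = p0[None, :] + np.outer(s * L, d)
        # symmetric circular-arc bow, perpendicular to the fascicle in the
        # plane spanned by the fascicle and the x axis: leaves the chord
        # direction (and hence the chord pennation angle) unchanged
        perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        bow = sagitta_frac * L * 4.0 * s * (1.0 - s)
        pts = chord + np.outer(bow, perp)
        if noise.digitizer_sd > 0:
            pts = pts + rng.normal(0.0, noise.digitizer_sd, size=pts.shape)
        fascicles.append(Fascicle(points=pts, label=muscle))

    return FascicleSet(
        fascicles=fascicles, origins=origin[None, :], insertions=insertion[None, :],
        animal="synthetic", meta={"seed": seed, "template": template,
                                  "ankle_deg": 90.0, "knee_deg": 90.0})


# -- directory export / import ------------------------------------------------

def save_experiment_set(expset: ExperimentSet, directory: str | Path) -> None:
    """Write an experiment set as CSV traces plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "muscle": expset.muscle,
        "seed": expset.seed,
        "noise": asdict(expset.noise),
        "anatomy": expset.anatomy,
        "isometric_keys": expset.isometric_keys,
        "isotonic_keys": expset.isotonic_keys,
        "quick_release_key": expset.quick_release_key,
        "tetanus_key": expset.tetanus_key,
        "history_groups": {f"{v:g}|{d}": list(pair)
                           for (v, d), pair in expset.history_groups.items()},
        "traces": {},
    }
    for key, tr in expset.traces.items():
        fname = f"{key}.csv"
        tr.to_csv(directory / fname)
        proto = tr.meta.get("protocol")
        manifest["traces"][key] = {
            "file": fname,
            "protocol": {k: v for k, v in asdict(proto).items()} if proto else None,
        }
    if expset.passive_points is not None:
        pd.DataFrame(expset.passive_points, columns=["l_MTC", "F"]).to_csv(
            directory / "passive_points.csv", index=False)
        manifest["passive_points"] = "passive_points.csv"
    if expset.truth is not None:
        save_parameters(expset.truth, directory / "ground_truth.toml")
        manifest["ground_truth"] = "ground_truth.toml"
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_experiment_set(directory: str | Path) -> ExperimentSet:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    traces = {}
    for key, entry in manifest["traces"].items():
        tr = SimulationTrace.from_csv(directory / entry["file"])
        if entry.get("protocol"):
            tr.meta["protocol"] = ProtocolSpec(**entry["protocol"])
        traces[key] = tr
    passive = None
    if manifest.get("passive_points"):
        passive = pd.read_csv(directory / manifest["passive_points"]).to_numpy()
    truth = None
    if manifest.get("ground_truth"):
        truth = load_parameters(directory / manifest["ground_truth"])
    groups = {}
    for gk, pair in (manifest.get("history_groups") or {}).items():
        v, d = gk.split("|")
        groups[(float(v), d)] = tuple(pair)
    noise = NoiseModel(**manifest["noise"])
    return ExperimentSet(
        muscle=manifest["muscle"], truth=truth, traces=traces,
        isometric_keys=manifest.get("isometric_keys") or [],
        passive_points=passive,
        isotonic_keys=manifest.get("isotonic_keys") or [],
        quick_release_key=manifest.get("quick_release_key"),
        tetanus_key=manifest.get("tetanus_key"),
        history_groups=groups,
        anatomy=manifest.get("anatomy") or {},
        noise=noise, seed=manifest.get("seed"))
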