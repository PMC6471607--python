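"""Seeded generator of labelled IMU + force-plate chair-rise sessions.

The generator emits the canonical chair-rise morphology: a sitting baseline
at resting weight, a brief flexion dip of the vertical force while the
subject gains momentum, a surge past body weight around seat-off with an
overshoot proportional to the subject's dynamics, a decay through a sub-body-
weight minimum, a return to body weight at full stand with a damped
stabilization oscillation, a mirrored (slightly slower) descent, five such
cycles, and non-test activity (a walking surrogate, quiet sitting) around
the test.  IMU and force channels are derived from the same latent phase
timeline, so cross-sensor alignment is consistent by construction.

All waveforms are sums of raised-cosine pieces between control points:
smooth, integrable, and analytically invertible, which lets the generator
report exact ground-truth phase times (seat-off, force peak, full stand) in
``SessionBundle.meta``.

A subject is parameterized by a scalar ``fitness`` in [0, 1]:

* per-rise duration maps linearly to 2.0 s (fitness 0) ... 0.8 s (fitness 1)
* force overshoot maps to 0.05 ... 0.35 of body weight (fitter subjects show
  a larger dynamic range)
* mediolateral sway scales with 1 - fitness (less fit subjects sway more)

Descents take 1.1x the rise duration.  The fraction of body weight resting
on the feet while seated defaults to 0.35.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, ParameterError, ValidationError
from .io import (
    DYNAMIC,
    GRAVITY,
    SIT,
    SIT_STAND,
    STAND,
    STAND_SIT,
    ForcePlateRecording,
    ImuRecording,
    LabelTrack,
    SessionBundle,
)

IMU_RATE = 100.0
FORCE_RATE = 200.0

#: descent duration as a multiple of the rise duration
DESCENT_FACTOR = 1.1


@dataclass(frozen=True)
class SubjectProfile:
    """Latent subject parameters driving the waveform generator."""

    body_mass: float = 78.8           # kg (study-population mean)
    resting_fraction: float = 0.35    # fraction of weight on feet while seated
    fitness: float = 0.6              # 0 = frail, 1 = fit
    noise_sd: float = 0.15            # accelerometer noise SD, m/s^2
    seed: int = 0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be positive")
        if not 0 < self.resting_fraction < 1:
            raise ValidationError("resting_fraction must lie in (0, 1)")
        if not 0 <= self.fitness <= 1:
            raise ValidationError("fitness must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def body_weight_n(self) -> float:
        return self.body_mass * GRAVITY

    @property
    def resting_weight_n(self) -> float:
        return self.resting_fraction * self.body_weight_n

    @property
    def rise_s(self) -> float:
        """Nominal per-rise duration: linear map fitness -> 2.0 ... 0.8 s."""
        return 2.0 - 1.2 * self.fitness

    @property
    def overshoot_frac(self) -> float:
        """Nominal force overshoot as a fraction of body weight."""
        return 0.05 + 0.30 * self.fitness

    @property
    def sway(self) -> float:
        return 1.0 - self.fitness


@dataclass(frozen=True)
class CyclePlan:
    """Per-cycle timing and dynamics of one rise-descent cycle."""

    rise_s: float
    stand_hold_s: float
    descent_s: float
    sit_hold_s: float
    overshoot_frac: float

    def __post_init__(self) -> None:
        for name in ("rise_s", "stand_hold_s", "descent_s", "sit_hold_s"):
            if getattr(self, name) < 0 or (name in ("rise_s", "descent_s")
                                           and getattr(self, name) <= 0):
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.overshoot_frac < 1:
            raise ValidationError("overshoot_frac must lie in (0, 1)")


@dataclass(frozen=True)
class SessionScript:
    """Ordered activity plan for one session.

    ``pre`` and ``post`` are (label, duration) pairs of non-test activity
    surrounding the 5CRT block.  The plan and the emitted ground-truth label
    track agree exactly.
    """

    cycles: tuple[CyclePlan, ...]
    pre: tuple[tuple[str, float], ...] = (("STAND", 3.0), ("DYNAMIC", 2.5),
                                          ("SIT", 6.0))
    post: tuple[tuple[str, float], ...] = (("SIT", 3.0), ("DYNAMIC", 2.0),
                                           ("STAND", 3.0))
    include_final_descent: bool = True

    def __post_init__(self) -> None:
        if len(self.cycles) < 1:
            raise ValidationError("script needs at least one cycle")
        for label, dur in self.pre + self.post:
            if dur <= 0:
                raise ValidationError("activity durations must be positive")
            if label not in (SIT, STAND, DYNAMIC):
                raise ValidationError(f"unsupported surrounding activity {label!r}")

    @classmethod
    def from_profile(cls, profile: SubjectProfile,
                     n_cycles: int = 5,
                     fatigue_slope: float = 0.02) -> "SessionScript":
        """Build the default five-cycle script for a subject.

        Cycle durations jitter mildly around the profile's nominal rise
        duration and slow down by ``fatigue_slope`` per cycle, echoing the
        late-test fatigue seen in real executions.
        """
        rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 17]))
        cycles = []
        for i in range(n_cycles):
            fatigue = 1.0 + fatigue_slope * i
            rise = profile.rise_s * fatigue * (1.0 + 0.03 * rng.standard_normal())
            descent = DESCENT_FACTOR * profile.rise_s * fatigue * (
                1.0 + 0.03 * rng.standard_normal())
            stand_hold = max(0.28, 0.38 * (1.0 + 0.2 * rng.standard_normal()))
            sit_hold = max(0.10, 0.22 * (1.0 + 0.2 * rng.standard_normal()))
            o = float(np.clip(profile.overshoot_frac
                              * (1.0 + 0.05 * rng.standard_normal()), 0.02, 0.6))
            cycles.append(CyclePlan(max(0.4, rise), stand_hold,
                                    max(0.4, descent), sit_hold, o))
        pre = ((STAND, 2.8 + 0.6 * rng.random()),
               (DYNAMIC, 2.2 + 0.6 * rng.random()),
               (SIT, 5.5 + 1.5 * rng.random()))
        post = ((SIT, 2.5 + 1.0 * rng.random()),
                (DYNAMIC, 1.8 + 0.5 * rng.random()),
                (STAND, 2.8 + 0.6 * rng.random()))
        return cls(cycles=tuple(cycles), pre=pre, post=post)

    def events(self) -> list[tuple[str, float, float, int | None, CyclePlan | None]]:
        """Flatten the plan into (label, t0, t1, cycle_index, plan) events."""
        out: list[tuple[str, float, float, int | None, CyclePlan | None]] = []
        t = 0.0

        def push(label: str, dur: float, ci: int | None = None,
                 plan: CyclePlan | None = None) -> None:
            nonlocal t
            out.append((label, t, t + dur, ci, plan))
            t += dur

        for label, dur in self.pre:
            push(label, dur)
        n = len(self.cycles)
        for i, c in enumerate(self.cycles):
            last = i == n - 1
            push(SIT_STAND, c.rise_s, i, c)
            if not last or self.include_final_descent:
                push(STAND, c.stand_hold_s, i, c)
                push(STAND_SIT, c.descent_s, i, c)
                if not last:
                    push(SIT, c.sit_hold_s, i, c)
        for label, dur in self.post:
            push(label, dur)
        return out

    def to_label_track(self) -> LabelTrack:
        return LabelTrack((t0, t1, lab) for lab, t0, t1, _, _ in self.events())

    @property
    def total_duration_s(self) -> float:
        """Ground-truth stopwatch duration: first rise onset to fifth rise end."""
        rises = [(t0, t1) for lab, t0, t1, _, _ in self.events() if lab == SIT_STAND]
        return rises[-1][1] - rises[0][0]


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _cosine_nodes(u: np.ndarray, nodes_u: np.ndarray, nodes_v: np.ndarray) -> np.ndarray:
    """Piecewise raised-cosine interpolation through control points."""
    u = np.clip(u, nodes_u[0], nodes_u[-1])
    idx = np.clip(np.searchsorted(nodes_u, u, side="right") - 1, 0, len(nodes_u) - 2)
    u0, u1 = nodes_u[idx], nodes_u[idx + 1]
    v0, v1 = nodes_v[idx], nodes_v[idx + 1]
    s = (u - u0) / (u1 - u0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))


def _invert_cosine(v0: float, v1: float, u0: float, u1: float, target: float) -> float:
    """Phase fraction u where the raised-cosine piece crosses ``target``."""
    s = (target - v0) / (v1 - v0)
    s = min(max(s, 0.0), 1.0)
    return u0 + (u1 - u0) * math.acos(1.0 - 2.0 * s) / math.pi


def _smooth01(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _flex_bump(u: np.ndarray, center: float = 0.35, width: float = 0.7) -> np.ndarray:
    arg = (u - center) / width
    out = np.cos(np.pi * arg) ** 2
    out[np.abs(arg) >= 0.5] = 0.0
    return out


@dataclass(frozen=True)
class _Shape:
    """Subject-specific waveform shape parameters (drawn once per subject)."""

    dip_u: float
    peak_u: float
    under_u: float
    dip_frac: float
    undershoot_rel: float
    stab_freq: float
    stab_amp_frac: float
    sit_tilt_deg: float
    flex_amp_deg: float

    @classmethod
    def draw(cls, profile: SubjectProfile) -> "_Shape":
        rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 29]))
        u = rng.random(6)
        return cls(
            dip_u=0.12 + 0.06 * u[0],
            peak_u=0.42 + 0.06 * u[1],
            under_u=0.70 + 0.05 * u[2],
            dip_frac=0.03 + 0.02 * u[3],
            undershoot_rel=0.30 + 0.15 * u[4],
            stab_freq=1.8 + 0.8 * u[5],
            stab_amp_frac=0.004 + 0.011 * profile.sway,
            sit_tilt_deg=10.0 + 8.0 * rng.random(),
            flex_amp_deg=8.0 + 10.0 * profile.fitness,
        )

    def rise_nodes(self, rw: float, bw: float, overshoot_frac: float
                   ) -> tuple[np.ndarray, np.ndarray]:
        under = bw * (1.0 - max(0.03, self.undershoot_rel * overshoot_frac))
        nodes_u = np.array([0.0, self.dip_u, self.peak_u, self.under_u, 1.0])
        nodes_v = np.array([rw, rw - self.dip_frac * bw,
                            (1.0 + overshoot_frac) * bw, under, bw])
        return nodes_u, nodes_v


def _rise_truth(shape: _Shape, rw: float, bw: float, o: float,
                t0: float, dur: float) -> dict:
    """Analytic ground-truth phase times for one programmed rise."""
    nodes_u, nodes_v = shape.rise_nodes(rw, bw, o)
    theta = rw + 0.5 * (bw - rw)
    u_seat = _invert_cosine(nodes_v[1], nodes_v[2], nodes_u[1], nodes_u[2], theta)
    u_full = _invert_cosine(nodes_v[3], nodes_v[4], nodes_u[3], nodes_u[4], 0.98 * bw)
    return {
        "start": t0,
        "end": t0 + dur,
        "seat_off_t": t0 + u_seat * dur,
        "peak_t": t0 + shape.peak_u * dur,
        "peak_N": (1.0 + o) * bw,
        "full_stand_t": t0 + u_full * dur,
        "overshoot_N": o * bw,
    }


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _force_profile(t: np.ndarray, events, shape: _Shape, rw: float, bw: float
                   ) -> np.ndarray:
    """Noise-free vertical force as a function of time (any sample grid)."""
    f = np.full_like(t, rw)
    prev_val = rw
    for k, (label, t0, t1, _, plan) in enumerate(events):
        m = (t >= t0) & (t < t1) if k < len(events) - 1 else (t >= t0) & (t <= t1)
        dur = t1 - t0
        u = (t[m] - t0) / dur
        if label == SIT:
            f[m] = rw
            prev_val = rw
        elif label == STAND:
            tau = 0.5
            f[m] = bw + shape.stab_amp_frac * bw * np.sin(
                2 * np.pi * shape.stab_freq * (t[m] - t0)) * np.exp(-(t[m] - t0) / tau)
            prev_val = bw
        elif label == SIT_STAND:
            nodes_u, nodes_v = shape.rise_nodes(rw, bw, plan.overshoot_frac)
            f[m] = _cosine_nodes(u, nodes_u, nodes_v)
            prev_val = bw
        elif label == STAND_SIT:
            nodes_u, nodes_v = shape.rise_nodes(rw, bw, plan.overshoot_frac)
            f[m] = _cosine_nodes(1.0 - u, nodes_u, nodes_v)
            prev_val = rw
        else:  # DYNAMIC walking surrogate: ramp in/out, oscillate about BW
            nxt = events[k + 1][0] if k + 1 < len(events) else None
            exit_val = rw if nxt in (SIT, None) else bw
            ramp = min(0.3, 0.2 * dur)
            env = np.minimum(np.minimum((t[m] - t0) / ramp, (t1 - t[m]) / ramp), 1.0)
            base = prev_val + (exit_val - prev_val) * _smooth01(u)
            osc = 0.05 * bw * np.sin(2 * np.pi * 1.9 * (t[m] - t0)) \
                + 0.02 * bw * np.sin(2 * np.pi * 3.3 * (t[m] - t0) + 1.0)
            f[m] = base + env * osc + env * (bw - base) * 0.0
            prev_val = exit_val
    return f


def _tilt_profile(t: np.ndarray, events, shape: _Shape) -> np.ndarray:
    """Sensor pitch tilt (degrees, forward positive) over time."""
    tilt = np.full_like(t, shape.sit_tilt_deg)
    for k, (label, t0, t1, _, _) in enumerate(events):
        m = (t >= t0) & (t < t1) if k < len(events) - 1 else (t >= t0) & (t <= t1)
        dur = t1 - t0
        u = (t[m] - t0) / dur
        if label == SIT:
            tilt[m] = shape.sit_tilt_deg
        elif label in (STAND, DYNAMIC):
            tilt[m] = 0.0
        elif label == SIT_STAND:
            tilt[m] = shape.sit_tilt_deg * (1.0 - _smooth01(u)) \
                + shape.flex_amp_deg * _flex_bump(u)
        elif label == STAND_SIT:
            tilt[m] = shape.sit_tilt_deg * _smooth01(u) \
                + shape.flex_amp_deg * _flex_bump(1.0 - u)
    return tilt


def _baseline_profile(t: np.ndarray, events, rw: float, bw: float) -> np.ndarray:
    """Quasi-static support force (chair + plate share) used to turn the
    force trace into center-of-mass acceleration."""
    base = np.full_like(t, rw)
    for k, (label, t0, t1, _, _) in enumerate(events):
        m = (t >= t0) & (t < t1) if k < len(events) - 1 else (t >= t0) & (t <= t1)
        u = (t[m] - t0) / (t1 - t0)
        if label == SIT:
            base[m] = rw
        elif label in (STAND, DYNAMIC):
            base[m] = bw
        elif label == SIT_STAND:
            base[m] = rw + (bw - rw) * _smooth01(u)
        elif label == STAND_SIT:
            base[m] = bw - (bw - rw) * _smooth01(u)
    return base


def generate_session(profile: SubjectProfile,
                     script: SessionScript | None = None) -> SessionBundle:
    """Generate one labelled session (IMU at 100 Hz, force at 200 Hz).

    Returns a :class:`SessionBundle` whose ``truth`` track equals the script
    exactly and whose ``meta`` carries the drawn parameters and analytic
    ground-truth phase times per rise (seat-off, peak, full stand,
    overshoot), plus the ground-truth stopwatch duration (first rise onset to
    fifth rise end).  Bit-identical for a fixed profile (seed) and script.
    """
    if script is None:
        script = SessionScript.from_profile(profile)
    shape = _Shape.draw(profile)
    events = script.events()
    total = events[-1][2]
    rw, bw = profile.resting_weight_n, profile.body_weight_n
    mass = profile.body_mass

    ss = np.random.SeedSequence([profile.seed, 97])
    rng_imu, rng_force = (np.random.default_rng(c) for c in ss.spawn(2))

    t_imu = np.arange(0.0, total, 1.0 / IMU_RATE)
    t_f = np.arange(0.0, total, 1.0 / FORCE_RATE)

    # --- force plate -------------------------------------------------------
    fv_clean = _force_profile(t_f, events, shape, rw, bw)
    noise_f = 10.0 * profile.noise_sd
    f_v = np.maximum(fv_clean + noise_f * rng_force.standard_normal(len(t_f)), 0.0)
    f_ml = np.zeros_like(t_f)
    f_ap = np.zeros_like(t_f)
    for k, (label, t0, t1, _, _) in enumerate(events):
        m = (t_f >= t0) & (t_f < t1) if k < len(events) - 1 else (t_f >= t0) & (t_f <= t1)
        u = (t_f[m] - t0) / (t1 - t0)
        if label in (SIT_STAND, STAND_SIT):
            f_ap[m] = 0.06 * bw * np.sin(np.pi * u) * (1 if label == SIT_STAND else -1)
            f_ml[m] = 8.0 * profile.sway * np.sin(2 * np.pi * 1.1 * (t_f[m] - t0))
        elif label == STAND:
            f_ml[m] = 12.0 * profile.sway * np.sin(
                2 * np.pi * 0.9 * (t_f[m] - t0)) * np.exp(-(t_f[m] - t0) / 0.8)
    f_ml += noise_f * rng_force.standard_normal(len(t_f))
    f_ap += noise_f * rng_force.standard_normal(len(t_f))

    force = ForcePlateRecording(
        t=t_f, f_v=f_v, f_ml=f_ml, f_ap=f_ap, sample_rate=FORCE_RATE,
        subject_id=profile.subject_id, body_weight=bw, resting_weight=rw)

    # --- IMU (same latent phase timeline) ----------------------------------
    fv_imu = _force_profile(t_imu, events, shape, rw, bw)
    base_imu = _baseline_profile(t_imu, events, rw, bw)
    tilt_deg = _tilt_profile(t_imu, events, shape)
    tilt_rad = np.radians(tilt_deg)

    acc_v = GRAVITY * np.cos(tilt_rad) + (fv_imu - base_imu) / mass
    acc_ap = GRAVITY * np.sin(tilt_rad)
    acc_ml = np.zeros_like(t_imu)
    gyr_ml = -np.gradient(tilt_deg, t_imu)
    gyr_v = np.zeros_like(t_imu)
    gyr_ap = np.zeros_like(t_imu)

    amp_dyn = 2.0 + 1.0 * profile.fitness
    for k, (label, t0, t1, _, _) in enumerate(events):
        m = (t_imu >= t0) & (t_imu < t1) if k < len(events) - 1 else \
            (t_imu >= t0) & (t_imu <= t1)
        u = (t_imu[m] - t0) / (t1 - t0)
        rel = t_imu[m] - t0
        if label == DYNAMIC:
            env = np.sin(np.pi * np.clip(u, 0, 1)) ** 2
            acc_v[m] += amp_dyn * env * np.sin(2 * np.pi * 1.9 * rel)
            acc_ap[m] += 0.6 * amp_dyn * env * np.sin(2 * np.pi * 2.3 * rel + 0.7)
            acc_ml[m] += 0.5 * amp_dyn * env * np.sin(2 * np.pi * 1.6 * rel + 1.9)
            gyr_v[m] += 35.0 * env * np.sin(2 * np.pi * 1.9 * rel + 0.3)
            gyr_ap[m] += 25.0 * env * np.sin(2 * np.pi * 1.4 * rel + 2.2)
        elif label in (SIT_STAND, STAND_SIT):
            sgn = 1.0 if label == SIT_STAND else -1.0
            acc_ap[m] += sgn * (0.8 + 1.5 * profile.fitness) * np.sin(2 * np.pi * u)
            acc_ml[m] += 0.25 * (0.2 + 0.6 * profile.sway) * np.sin(
                2 * np.pi * 1.3 * rel)
        elif label == STAND:
            acc_ml[m] += (0.2 + 0.6 * profile.sway) * np.sin(
                2 * np.pi * 0.9 * rel) * np.exp(-rel / 0.8)

    nsd = profile.noise_sd
    acc_v += nsd * rng_imu.standard_normal(len(t_imu))
    acc_ml += nsd * rng_imu.standard_normal(len(t_imu))
    acc_ap += nsd * rng_imu.standard_normal(len(t_imu))
    gsd = 5.0 * nsd
    gyr_v += gsd * rng_imu.standard_normal(len(t_imu))
    gyr_ml += gsd * rng_imu.standard_normal(len(t_imu))
    gyr_ap += gsd * rng_imu.standard_normal(len(t_imu))

    imu = ImuRecording(
        t=t_imu, acc_v=acc_v, acc_ml=acc_ml, acc_ap=acc_ap,
        gyr_v=gyr_v, gyr_ml=gyr_ml, gyr_ap=gyr_ap,
        sample_rate=IMU_RATE, subject_id=profile.subject_id)

    phases = [
        _rise_truth(shape, rw, bw, plan.overshoot_frac, t0, t1 - t0) | {"cycle": ci + 1}
        for (label, t0, t1, ci, plan) in events if label == SIT_STAND
    ]
    meta = {
        "profile": {
            "body_mass": profile.body_mass, "fitness": profile.fitness,
            "resting_fraction": profile.resting_fraction,
            "noise_sd": profile.noise_sd, "seed": profile.seed,
            "body_weight_N": bw, "resting_weight_N": rw,
        },
        "rise_phases": phases,
        "script_total_s": script.total_duration_s,
    }
    return SessionBundle(imu=imu, force=force, truth=script.to_label_track(),
                         stopwatch_5crt=script.total_duration_s, meta=meta)


def generate_cohort(n: int, seed: int = 0,
                    duration_range: tuple[float, float] = (9.2, 16.8),
                    noise_range: tuple[float, float] = (0.05, 0.25),
                    ) -> list[SessionBundle]:
    """Generate ``n`` subjects with stratified total test durations.

    Target total durations are drawn latin-hypercube style over
    ``duration_range`` (one draw per equal stratum, order shuffled), so that
    for realistic cohort sizes the induced distribution has a mean near the
    study-population value (~12-13 s) and spans the 4-, 3- and 2-point
    scoring bands.  Fitness, rise duration and hold lengths are then derived
    from each subject's target duration.
    """
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    lo, hi = duration_range
    if not 0 < lo < hi:
        raise ParameterError("invalid duration_range")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    strata = (np.arange(n) + rng.random(n)) / n
    targets = lo + rng.permutation(strata) * (hi - lo)
    bundles = []
    for i, target in enumerate(targets):
        rho = 0.10 + 0.08 * rng.random()           # fraction of T spent in holds
        rise = (1.0 - rho) * target / (5 + 4 * DESCENT_FACTOR)
        fitness = float(np.clip((2.0 - rise) / 1.2, 0.05, 0.98))
        mass = float(np.clip(rng.normal(78.8, 12.4), 55.0, 101.0))
        noise = float(noise_range[0] + (noise_range[1] - noise_range[0]) * rng.random())
        sub_seed = int(rng.integers(0, 2**31 - 1))
        profile = SubjectProfile(body_mass=mass, fitness=fitness, noise_sd=noise,
                                 seed=sub_seed, subject_id=f"S{i:02d}")
        cycles = []
        for c in range(5):
            jit = 1.0 + 0.03 * rng.standard_normal()
            fatigue = 1.0 + 0.02 * c
            stand_hold = max(0.25, 0.15 * rho * target * (1.0 + 0.15 * rng.standard_normal()))
            sit_hold = max(0.08, 0.10 * rho * target * (1.0 + 0.15 * rng.standard_normal()))
            o = float(np.clip(profile.overshoot_frac
                              * (1.0 + 0.05 * rng.standard_normal()), 0.02, 0.6))
            cycles.append(CyclePlan(
                rise_s=max(0.4, rise * jit * fatigue),
                stand_hold_s=stand_hold,
                descent_s=max(0.4, DESCENT_FACTOR * rise * fatigue
                              * (1.0 + 0.03 * rng.standard_normal())),
                sit_hold_s=sit_hold,
                overshoot_frac=o))
        script = SessionScript(
            cycles=tuple(cycles),
            pre=((STAND, 2.8 + 0.6 * rng.random()),
                 (DYNAMIC, 2.2 + 0.6 * rng.random()),
                 (SIT, 5.5 + 1.5 * rng.random())),
            post=((SIT, 2.5 + 1.0 * rng.random()),
                  (DYNAMIC, 1.8 + 0.5 * rng.random()),
                  (STAND, 2.8 + 0.6 * rng.random())))
        bundles.append(generate_session(profile, script))
    return bundles


CORRUPTION_MODES = ("interrupt_cycle", "inject_dynamic", "truncate")


def corrupt_session(bundle: SessionBundle, mode: str) -> SessionBundle:
    """Return a copy whose truth track violates the valid-test grammar.

    ``interrupt_cycle`` drops one rise (relabels the 3rd SIT_STAND as SIT),
    ``inject_dynamic`` relabels a mid-test static hold as DYNAMIC, and
    ``truncate`` cuts the session right after the 3rd rise.  Negative
    controls for the detector; the stopwatch reference is cleared.
    """
    if mode not in CORRUPTION_MODES:
        raise ParameterError(f"unknown corruption mode {mode!r}; "
                             f"choose from {CORRUPTION_MODES}")
    if bundle.truth is None:
        raise InputError("bundle has no truth track to corrupt")
    segs = list(bundle.truth.segments)
    rise_idx = [i for i, s in enumerate(segs) if s.label == SIT_STAND]
    if len(rise_idx) < 5:
        raise InputError("bundle does not contain a full five-rise test")

    if mode == "interrupt_cycle":
        i = rise_idx[2]
        segs[i] = segs[i]._replace(label=SIT)
        track = LabelTrack(segs)
        return SessionBundle(imu=bundle.imu, force=bundle.force, truth=track,
                             stopwatch_5crt=None, meta=dict(bundle.meta))
    if mode == "inject_dynamic":
        inside = range(rise_idx[0] + 1, rise_idx[-1])
        holds = [i for i in inside if segs[i].label in (SIT, STAND)]
        if not holds:
            raise InputError("no static hold inside the test to corrupt")
        i = holds[len(holds) // 2]
        segs[i] = segs[i]._replace(label=DYNAMIC)
        track = LabelTrack(segs)
        return SessionBundle(imu=bundle.imu, force=bundle.force, truth=track,
                             stopwatch_5crt=None, meta=dict(bundle.meta))
    # truncate after the third rise
    cut = segs[rise_idx[2]].end
    kept = [s for s in segs if s.end <= cut + 1e-9]
    track = LabelTrack(kept)
    imu = bundle.imu.crop(bundle.imu.t[0], cut)
    force = bundle.force.crop(bundle.force.t[0], cut) if bundle.force is not None else None
    return SessionBundle(imu=imu, force=force, truth=track,
                         stopwatch_5crt=None, meta=dict(bundle.meta))
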