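"""Synthetic participants and trials with known ground truth.

The simulator stands in for the study's raw data. Each agent pre-programs
a smooth reach covering the 27.7-cm groove in a planned 200-250 ms,
launched so that the effector center reaches the strike-zone center at the
*predicted* (base-velocity) target arrival — perturbations are unknowable
before launch. Timing (aim) noise shifts the launch; a perturbed trial may
then trigger online corrections.

Reach profiles
--------------
The pre-programmed reach uses a beta-family velocity profile

    v(tau) ∝ tau^a (1 - tau)^b,   a = 4p, b = 4(1 - p),

which is exactly the minimum-jerk profile for p = 0.5 (a = b = 2) and
shifts the velocity peak to relative time p otherwise; position is the
regularized incomplete beta function. This gives the agent a planned
relative time-to-peak-velocity dial.

Corrections
-----------
A correction re-plans the remaining reach as a minimum-jerk (quintic)
segment that matches position, velocity, and acceleration at the
correction time and arrives at the strike line at the newly predicted
target arrival, scaled by a correction gain. Speeding up is a single
re-planned segment; slowing down brakes toward a near stop and
re-approaches (a superimposed pulse with negative net displacement would
leave the effector short of the line, so delay is modeled by re-planning).
Each correction leaves one extra qualifying valley in the acceleration
trace — the signature the kinematics module counts.

A separate composite generator (:func:`composite_trajectory`) builds
reaches as *superimposed* overlapping minimum-jerk pulses; it is the
ground-truth harness for detector-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize, special

from .errors import (ConfigurationError, InvalidParameterError,
                     NoCrossingError)
from .geometry import TargetState, TaskConfig, find_crossing
from .kinematics import Trajectory
from .protocol import (ExposureSchedule, ScheduleEntry, StabilizationCriterion,
                       assign_groups, check_stabilization,
                       generate_exposure_schedule)

__all__ = [
    "AgentParams",
    "AgentDistributions",
    "SimTrial",
    "SimParticipant",
    "StudyData",
    "minimum_jerk",
    "minimum_jerk_velocity",
    "minimum_jerk_acceleration",
    "plan_launch",
    "simulate_trial",
    "simulate_study",
    "composite_trajectory",
]

VELOCITY_TRIGGER = 5.0       # cm/s: effector speed defining "movement onset"
MIN_REPLAN_S = 0.025         # floor on the lead to a re-planned crossing
MIN_LEAD_S = 0.030           # a correction needs this much movement left
MIN_SUBMOVE_S = 0.100        # floor on a corrective submovement's duration
BRAKE_FRACTION = 0.4         # fraction of remaining distance used to brake
V_APPROACH_PEAK_MIN = 20.0   # cm/s floor on a re-approach's peak velocity
MIN_APPROACH_S = 0.060       # floor on a re-approach's duration
MIN_IMPROVE_S = 0.020        # a correction must shift arrival by this much
RELEASE_S = 0.040            # drive-release duration preceding a boost
FOLLOW_S = 0.080             # follow-through duration past the strike line


# ---------------------------------------------------------------------------
# analytic primitives
# ---------------------------------------------------------------------------

def minimum_jerk(d: float, mt: float, t):
    """Minimum-jerk position d*(10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/mt.

    ``t`` and ``mt`` must share a unit; values outside [0, mt] clamp to the
    endpoints (at rest before onset, at the target after completion).
    """
    if mt <= 0:
        raise InvalidParameterError("mt must be > 0")
    tau = np.clip(np.asarray(t, dtype=float) / mt, 0.0, 1.0)
    out = d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return out if out.ndim else float(out)


def minimum_jerk_velocity(d: float, mt: float, t):
    """Analytic derivative of :func:`minimum_jerk`; peak 1.875*d/mt at mt/2."""
    if mt <= 0:
        raise InvalidParameterError("mt must be > 0")
    t_arr = np.asarray(t, dtype=float)
    tau = t_arr / mt
    inside = (tau >= 0) & (tau <= 1)
    tau = np.clip(tau, 0.0, 1.0)
    out = np.where(inside, d / mt * 30 * tau**2 * (1 - tau) ** 2, 0.0)
    return out if out.ndim else float(out)


def minimum_jerk_acceleration(d: float, mt: float, t):
    t_arr = np.asarray(t, dtype=float)
    tau = t_arr / mt
    inside = (tau >= 0) & (tau <= 1)
    tau = np.clip(tau, 0.0, 1.0)
    out = np.where(inside, d / mt**2 * (60 * tau - 180 * tau**2 + 120 * tau**3), 0.0)
    return out if out.ndim else float(out)


class _BetaReach:
    """Beta-family reach segment from rest to rest over [t0, t0+mt]."""

    def __init__(self, t0: float, mt: float, d: float, x_start: float,
                 tpv_frac: float = 0.5):
        if not 0.2 <= tpv_frac <= 0.8:
            raise InvalidParameterError("tpv_frac must be in [0.2, 0.8]")
        self.t0, self.t1 = t0, t0 + mt
        self.mt, self.d, self.x_start = mt, d, x_start
        self.a_shape = 4.0 * tpv_frac
        self.b_shape = 4.0 * (1.0 - tpv_frac)
        self._norm = special.beta(self.a_shape + 1, self.b_shape + 1)

    def _tau(self, t):
        return np.clip((np.asarray(t, dtype=float) - self.t0) / self.mt, 0.0, 1.0)

    def pos(self, t):
        tau = self._tau(t)
        return self.x_start + self.d * special.betainc(
            self.a_shape + 1, self.b_shape + 1, tau)

    def vel(self, t):
        tau = self._tau(t)
        g = np.where((tau > 0) & (tau < 1),
                     tau**self.a_shape * (1 - tau)**self.b_shape / self._norm, 0.0)
        return self.d / self.mt * g

    def acc(self, t):
        tau = self._tau(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            core = (tau**(self.a_shape - 1) * (1 - tau)**(self.b_shape - 1)
                    * (self.a_shape * (1 - tau) - self.b_shape * tau))
        g = np.where((tau > 0) & (tau < 1), core / self._norm, 0.0)
        return self.d / self.mt**2 * g

    def trigger_time(self, v_trigger: float) -> float:
        """First time the segment's speed exceeds ``v_trigger`` cm/s."""
        peak = float(self.vel(self.t0 + self.mt * (self.a_shape / 4.0)))
        if v_trigger >= peak:
            raise InvalidParameterError("trigger above peak velocity")
        f = lambda tau: (self.d / self.mt
                         * tau**self.a_shape * (1 - tau)**self.b_shape
                         / self._norm) - v_trigger
        tau_star = optimize.brentq(f, 1e-9, self.a_shape / 4.0)
        return self.t0 + tau_star * self.mt


class _Quintic:
    """Quintic segment with full boundary state at both ends."""

    def __init__(self, t0: float, duration: float,
                 start: Tuple[float, float, float],
                 end: Tuple[float, float, float]):
        if duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        self.t0, self.t1 = t0, t0 + duration
        T = duration
        x0, v0, a0 = start
        x1, v1, a1 = end
        c0, c1, c2 = x0, v0, a0 / 2.0
        A = np.array([
            [T**3, T**4, T**5],
            [3 * T**2, 4 * T**3, 5 * T**4],
            [6 * T, 12 * T**2, 20 * T**3],
        ])
        rhs = np.array([
            x1 - (c0 + c1 * T + c2 * T**2),
            v1 - (c1 + 2 * c2 * T),
            a1 - 2 * c2,
        ])
        c3, c4, c5 = np.linalg.solve(A, rhs)
        self.c = np.array([c0, c1, c2, c3, c4, c5])

    def _s(self, t):
        return np.clip(np.asarray(t, dtype=float) - self.t0, 0.0, self.t1 - self.t0)

    def pos(self, t):
        s = self._s(t)
        return sum(ck * s**k for k, ck in enumerate(self.c))

    def vel(self, t):
        s = self._s(t)
        inside = (np.asarray(t, dtype=float) >= self.t0) & (np.asarray(t) <= self.t1)
        val = sum(k * ck * s**(k - 1) for k, ck in enumerate(self.c) if k >= 1)
        return np.where(inside, val, 0.0)

    def acc(self, t):
        s = self._s(t)
        inside = (np.asarray(t, dtype=float) >= self.t0) & (np.asarray(t) <= self.t1)
        val = sum(k * (k - 1) * ck * s**(k - 2)
                  for k, ck in enumerate(self.c) if k >= 2)
        return np.where(inside, val, 0.0)


class _PiecewiseReach:
    """Ordered reach segments; at rest before the first and after the last."""

    def __init__(self, x_rest: float = 0.0):
        self.segments: List = []
        self.x_rest = x_rest

    @property
    def end_time(self) -> float:
        return self.segments[-1].t1 if self.segments else 0.0

    @property
    def end_pos(self) -> float:
        return float(self.segments[-1].pos(self.segments[-1].t1)) \
            if self.segments else self.x_rest

    def append(self, seg) -> None:
        self.segments.append(seg)

    def truncate(self, t_c: float) -> None:
        """Drop segments entirely after ``t_c`` (re-plan supersedes them)."""
        self.segments = [s for s in self.segments if s.t0 < t_c]

    def state(self, t: float) -> Tuple[float, float, float]:
        for seg in reversed(self.segments):
            if t >= seg.t0:
                if t <= seg.t1:
                    return (float(seg.pos(t)), float(seg.vel(t)), float(seg.acc(t)))
                return (float(seg.pos(seg.t1)), 0.0, 0.0)
        return (self.x_rest, 0.0, 0.0)

    def sample(self, t_grid: np.ndarray) -> np.ndarray:
        x = np.full_like(t_grid, self.x_rest, dtype=float)
        for seg in self.segments:
            m = t_grid >= seg.t0
            x[m] = seg.pos(t_grid[m])
            after = t_grid > seg.t1
            x[after] = seg.pos(seg.t1)
        return x


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentParams:
    """One simulated participant's control policy.

    These are calibration choices that reproduce the qualitative group
    structure (the superstabilization group corrects more often and peaks
    earlier under perturbation); they are not estimates of any real
    participant.
    """

    group: str                           # "SG" | "SSG"
    planned_mt: float = 225.0            # ms, drawn U(200, 250) at study level
    aim_noise_sd: float = 3.0            # cm of timing-equivalent aim error
    correction_probability: float = 0.3  # per perturbed trial
    correction_latency: float = 150.0    # ms after perturbation onset
    correction_gain: float = 0.8         # fraction of predicted error removed
    max_corrections: int = 2
    tpv_baseline: float = 50.0           # planned tPV%, unperturbed
    tpv_perturbed_shift: float = 0.0     # planned tPV% shift on perturbed trials

    def __post_init__(self) -> None:
        if self.group not in ("SG", "SSG"):
            raise InvalidParameterError("group must be 'SG' or 'SSG'")
        if not 0.0 <= self.correction_probability <= 1.0:
            raise InvalidParameterError("correction_probability must be in [0,1]")
        if self.correction_latency <= 0:
            raise InvalidParameterError("correction_latency must be > 0")
        if not 0 <= self.max_corrections <= 3:
            raise InvalidParameterError("max_corrections must be in 0..3")
        if not 0.0 < self.correction_gain <= 1.0:
            raise InvalidParameterError("correction_gain must be in (0,1]")
        if self.aim_noise_sd < 0 or self.planned_mt <= 0:
            raise InvalidParameterError("invalid noise or planned_mt")


def sg_agent(**over) -> AgentParams:
    base = dict(group="SG", correction_probability=0.3, tpv_perturbed_shift=0.0)
    base.update(over)
    return AgentParams(**base)


def ssg_agent(**over) -> AgentParams:
    base = dict(group="SSG", correction_probability=0.8,
                tpv_perturbed_shift=-10.0)
    base.update(over)
    return AgentParams(**base)


@dataclass(frozen=True)
class AgentDistributions:
    """Population distributions agents are drawn from, per group.

    Group means follow the defaults above; between-participant jitter is
    mild so that group contrasts dominate individual differences.
    """

    correction_probability: Dict[str, float] = field(
        default_factory=lambda: {"SG": 0.3, "SSG": 0.8})
    tpv_perturbed_shift: Dict[str, float] = field(
        default_factory=lambda: {"SG": 0.0, "SSG": -10.0})
    correction_probability_sd: float = 0.08
    planned_mt_range: Tuple[float, float] = (200.0, 250.0)
    aim_noise_sd_mean: float = 3.0
    aim_noise_sd_sd: float = 0.8
    correction_latency_mean: float = 150.0
    correction_latency_sd: float = 20.0
    correction_gain_mean: float = 0.8
    correction_gain_sd: float = 0.05
    tpv_baseline: float = 50.0
    max_corrections: int = 2

    def draw(self, group: str, rng: np.random.Generator) -> AgentParams:
        return AgentParams(
            group=group,
            planned_mt=float(rng.uniform(*self.planned_mt_range)),
            aim_noise_sd=float(np.clip(
                rng.normal(self.aim_noise_sd_mean, self.aim_noise_sd_sd),
                0.5, 8.0)),
            correction_probability=float(np.clip(
                rng.normal(self.correction_probability[group],
                           self.correction_probability_sd), 0.0, 1.0)),
            correction_latency=float(np.clip(
                rng.normal(self.correction_latency_mean,
                           self.correction_latency_sd), 80.0, 300.0)),
            correction_gain=float(np.clip(
                rng.normal(self.correction_gain_mean, self.correction_gain_sd),
                0.3, 1.0)),
            max_corrections=self.max_corrections,
            tpv_baseline=self.tpv_baseline,
            tpv_perturbed_shift=self.tpv_perturbed_shift[group],
        )


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class SimTrial:
    trajectory: Trajectory
    kind: str
    perturbation_ordinal: Optional[int]
    injected_corrections: int
    true_ce: float
    t_launch: float
    t_perturb: Optional[float]
    flags: List[str] = field(default_factory=list)


def plan_launch(agent: AgentParams, target: TargetState, cfg: TaskConfig,
                rng: Optional[np.random.Generator] = None,
                mt_override: Optional[float] = None) -> float:
    """Launch time so effector-center arrival coincides with the predicted
    (base-velocity) target-center arrival, plus aim noise.

    The prediction deliberately ignores any perturbation: the agent cannot
    know it before launch. Aim noise is specified as a spatial SD (cm) and
    converted to launch-time jitter through the base target speed.
    ``mt_override`` (s) replaces the agent's planned MT when the trial's
    planned profile is stretched.
    """
    mt_s = mt_override if mt_override is not None else agent.planned_mt / 1000.0
    t_arrival = target.start_time + cfg.target_travel_distance / target.base_velocity
    launch = t_arrival - mt_s
    if launch <= target.start_time:
        raise ConfigurationError("target too close: launch before target start")
    if rng is not None and agent.aim_noise_sd > 0:
        launch += rng.normal(0.0, agent.aim_noise_sd) / target.base_velocity
    return float(launch)


def _perturbed_velocity(kind: str, cfg: TaskConfig) -> Optional[float]:
    return {"control": None, "fast": cfg.fast_velocity,
            "slow": cfg.slow_velocity}[kind]


def simulate_trial(agent: AgentParams, entry: ScheduleEntry,
                   cfg: TaskConfig, rng: np.random.Generator,
                   pos_noise_sd: float = 0.05,
                   meta: Optional[Dict] = None) -> SimTrial:
    """Simulate one exposure trial and sample it at the task's 200 Hz.

    Order of randomness (fixed for determinism): aim noise, correction
    Bernoulli (perturbed trials only), positional noise.
    """
    flags: List[str] = []
    D = cfg.pen_travel_distance
    mt_s = agent.planned_mt / 1000.0
    perturbed = entry.kind != "control"
    # a lower planned tPV% means a LONGER deceleration tail, not a faster
    # start: the reach is stretched so the velocity peak stays at the same
    # absolute time while the approach slows — which is exactly what buys
    # time for feedback corrections
    base_frac = agent.tpv_baseline / 100.0
    tpv_frac = base_frac
    if perturbed:
        tpv_frac += agent.tpv_perturbed_shift / 100.0
    mt_plan = mt_s * base_frac / tpv_frac

    target0 = TargetState(start_time=0.0, base_velocity=cfg.base_velocity)
    launch = plan_launch(agent, target0, cfg, rng, mt_override=mt_plan)
    reach = _PiecewiseReach(x_rest=0.0)
    base = _BetaReach(launch, mt_plan, D, 0.0, tpv_frac=tpv_frac)
    reach.append(base)
    planned_cross = launch + mt_plan

    # perturbation trigger: first 200-Hz sample after effector speed > 5 cm/s
    t_perturb: Optional[float] = None
    target = target0
    if perturbed:
        t_trig = base.trigger_time(VELOCITY_TRIGGER)
        t_perturb = math.ceil(t_trig * cfg.sample_rate) / cfg.sample_rate
        target = TargetState(
            start_time=0.0, base_velocity=cfg.base_velocity,
            change_time=t_perturb,
            new_velocity=_perturbed_velocity(entry.kind, cfg),
        )

    injected = 0
    if perturbed:
        will_correct = rng.random() < agent.correction_probability
        t_new_arrival = target.arrival_time(cfg.target_travel_distance)
        if will_correct:
            for c in range(agent.max_corrections):
                t_c = t_perturb + (c + 1) * agent.correction_latency / 1000.0
                if t_c >= planned_cross - MIN_LEAD_S:
                    if injected == 0:
                        flags.append("correction_impossible")
                    break
                predicted_ce = (target.position(planned_cross)
                                - cfg.target_travel_distance)
                if abs(predicted_ce) <= cfg.strike_zone_halfwidth / 2.0:
                    break
                t_des = planned_cross + agent.correction_gain * (
                    t_new_arrival - planned_cross)
                x_c, v_c, a_c = reach.state(t_c)
                t_rem_nat = planned_cross - t_c
                if t_des < planned_cross:
                    # speed up: a corrective submovement of physiological
                    # duration that CROSSES the line at t_des and follows
                    # through past it (pen decelerates beyond the line).
                    # If drive is still high when the correction starts, a
                    # brief release precedes the boost — the agonist burst
                    # follows a partial let-off, which is also what makes
                    # the correction legible as an acceleration valley.
                    t_des = max(t_des, t_c + MIN_REPLAN_S)
                    a_scale = 5.77 * D / mt_plan**2
                    reach.truncate(t_c)
                    if t_des - t_c > RELEASE_S + 0.03:
                        # dip below the CURRENT drive so the burst is a
                        # discrete event whatever phase it lands in
                        x_r = x_c + v_c * RELEASE_S
                        state_r = (x_r, v_c, a_c - 0.3 * a_scale)
                        reach.append(_Quintic(t_c, RELEASE_S,
                                              (x_c, v_c, a_c), state_r))
                        t_b, s_b = t_c + RELEASE_S, t_des - t_c - RELEASE_S
                    else:
                        state_r = (x_c, v_c, a_c)
                        t_b, s_b = t_c, t_des - t_c
                    # drive to the line, crossing it at t_des at roughly the
                    # mean remaining speed, then follow through to rest
                    v_des = max((D - state_r[0]) / s_b, 0.0)
                    reach.append(_Quintic(t_b, s_b, state_r, (D, v_des, 0.0)))
                    reach.append(_Quintic(t_des, FOLLOW_S, (D, v_des, 0.0),
                                          (D + 0.4 * v_des * FOLLOW_S,
                                           0.0, 0.0)))
                    planned_cross = t_des
                else:
                    # delay: brake over part of the remaining distance,
                    # then a fresh re-approach timed as late as a still-
                    # discernible submovement allows (its peak velocity is
                    # floored, which caps the achievable delay — a long
                    # hang cannot be produced by a creeping approach)
                    t_rem_des = min(t_des - t_c, t_rem_nat + 0.5)
                    delta = D - x_c
                    if delta <= 0:
                        break
                    x_b = x_c + BRAKE_FRACTION * delta
                    t_brake = 2.0 * (x_b - x_c) / max(v_c, 1e-6)
                    amp = D - x_b
                    t_app_cap = 1.875 * amp / V_APPROACH_PEAK_MIN
                    t_app = min(t_rem_des - t_brake, t_app_cap)
                    new_cross = t_c + t_brake + t_app
                    if (t_app < MIN_APPROACH_S
                            or new_cross - planned_cross < MIN_IMPROVE_S):
                        # too little room (or gain) for a discrete delaying
                        # submovement: the agent cannot correct here
                        if injected == 0:
                            flags.append("correction_impossible")
                        break
                    reach.truncate(t_c)
                    reach.append(_Quintic(t_c, t_brake, (x_c, v_c, a_c),
                                          (x_b, 0.0, 0.0)))
                    reach.append(_Quintic(t_c + t_brake, t_app,
                                          (x_b, 0.0, 0.0), (D, 0.0, 0.0)))
                    planned_cross = new_cross
                injected += 1

    # ground-truth crossing: the final segment is constructed to put the
    # effector center on the line at planned_cross; a fine-grid scan only
    # guards against an earlier (overshooting) first passage
    t_fine = np.arange(launch, reach.end_time + 0.05, 1e-3)
    x_fine = reach.sample(t_fine)
    try:
        t_cross_true = min(find_crossing(t_fine, x_fine, D - 1e-9),
                           planned_cross)
    except NoCrossingError:
        t_cross_true = planned_cross        # tangential touch of the line
    true_ce = float(target.position(t_cross_true) - cfg.target_travel_distance)

    t_end = max(reach.end_time,
                target.arrival_time(cfg.target_travel_distance)) + 0.25
    t_grid = np.arange(0.0, t_end, 1.0 / cfg.sample_rate)
    x = reach.sample(t_grid)
    if pos_noise_sd > 0:
        x = x + rng.normal(0.0, pos_noise_sd, size=x.shape)

    trial_meta = {
        "kind": entry.kind,
        "trial_index": entry.index,
        "perturbation_ordinal": entry.perturbation_ordinal,
        "phase": "exposure",
        "group": agent.group,
        "base_velocity": cfg.base_velocity,
        "new_velocity": (_perturbed_velocity(entry.kind, cfg)
                         if perturbed else np.nan),
        "t_perturb": t_perturb if t_perturb is not None else np.nan,
        "t_launch": launch,
        "injected_corrections": injected,
        "true_ce": true_ce,
        "strike_x": D,
        "target_travel_distance": cfg.target_travel_distance,
        "target_start_time": 0.0,
    }
    if meta:
        trial_meta.update(meta)
    return SimTrial(
        trajectory=Trajectory(t_grid, x, trial_meta),
        kind=entry.kind, perturbation_ordinal=entry.perturbation_ordinal,
        injected_corrections=injected, true_ce=true_ce,
        t_launch=launch, t_perturb=t_perturb, flags=flags,
    )


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

@dataclass
class SimParticipant:
    participant: str
    sex: str
    group: str
    agent: AgentParams
    learning_attempts: int
    excluded: bool
    trials: List[SimTrial] = field(default_factory=list)


@dataclass
class StudyData:
    participants: List[SimParticipant]
    seed: int

    def included(self) -> List[SimParticipant]:
        return [p for p in self.participants if not p.excluded]


def _learning_phase(agent: AgentParams, criterion: StabilizationCriterion,
                    cfg: TaskConfig, rng: np.random.Generator
                    ) -> Tuple[int, bool]:
    """Outcome-level learning phase: hit/miss from the closed-form launch
    model (CE ~ Normal(0, aim_noise_sd)); returns (attempts, excluded)."""
    ces = rng.normal(0.0, max(agent.aim_noise_sd, 1e-9),
                     size=criterion.max_attempts)
    hits = np.abs(ces) <= criterion.error_bandwidth
    res = check_stabilization(hits.tolist(), criterion)
    if res.satisfied:
        return res.attempt_satisfied, False
    return criterion.max_attempts, True


def simulate_study(n_per_group: int, seed: int,
                   cfg: TaskConfig = TaskConfig(),
                   dists: AgentDistributions = AgentDistributions(),
                   pos_noise_sd: float = 0.05,
                   keep_trajectories: bool = True,
                   participant_hook=None) -> StudyData:
    """Simulate a full study: group assignment, learning to criterion,
    then the 129-trial exposure phase per participant.

    Deterministic for a fixed seed (independent child RNG streams per
    participant). ``participant_hook(SimParticipant)``, when given, is
    called as each participant completes; with ``keep_trajectories=False``
    trial trajectories are dropped after the hook runs, so large studies
    can stream.
    """
    if n_per_group < 2:
        raise ConfigurationError("need at least 2 participants per group")
    n_total = 2 * n_per_group
    ids = [f"P{i + 1:02d}" for i in range(n_total)]
    sexes = ["M" if i < n_total // 2 else "F" for i in range(n_total)]

    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    assignment = assign_groups(list(zip(ids, sexes)), assign_rng)
    # balanced strata guarantee n_per_group per group for even group sizes
    child_seeds = ss.spawn(n_total)

    criteria = {"SG": StabilizationCriterion.sg(),
                "SSG": StabilizationCriterion.ssg()}
    participants: List[SimParticipant] = []
    for pid, sex, child in zip(ids, sexes, child_seeds):
        rng = np.random.default_rng(child)
        group = assignment[pid]
        agent = dists.draw(group, rng)
        attempts, excluded = _learning_phase(agent, criteria[group], cfg, rng)
        part = SimParticipant(pid, sex, group, agent, attempts, excluded)
        if not excluded:
            schedule = generate_exposure_schedule(rng)
            for entry in schedule.entries:
                part.trials.append(simulate_trial(
                    agent, entry, cfg, rng, pos_noise_sd=pos_noise_sd,
                    meta={"participant": pid},
                ))
        if participant_hook is not None:
            participant_hook(part)
        if not keep_trajectories:
            part.trials = []
        participants.append(part)
    return StudyData(participants=participants, seed=seed)


# ---------------------------------------------------------------------------
# superimposed-pulse composites (detector ground truth)
# ---------------------------------------------------------------------------

def composite_trajectory(n_corrections: int,
                         rng: Optional[np.random.Generator] = None,
                         d_main: float = 24.0,
                         mt_main: float = 0.22,
                         correction_amplitude: Tuple[float, float] = (6.0, 9.0),
                         correction_duration: Tuple[float, float] = (0.11, 0.14),
                         first_onset: float = 0.16,
                         min_gap: float = 0.08,
                         pos_noise_sd: float = 0.0,
                         fs: float = 200.0) -> Trajectory:
    """A reach built from superimposed overlapping minimum-jerk pulses.

    One main pulse plus ``n_corrections`` corrective pulses whose onsets
    are spaced at least ``min_gap`` apart (default 80 ms), each overlapping
    its predecessor so velocity never rests between submovements. Pulse
    amplitudes and durations are drawn so each pulse's initial jerk
    exceeds the main reach's steepest deceleration slope — a corrective
    pulse that cannot bend the acceleration trace would leave no valley to
    find, by construction rather than by detector failure. The injected
    count is ground truth for detector-recovery tests, recorded in
    ``meta['injected_corrections']``.
    """
    if not 0 <= n_corrections <= 3:
        raise InvalidParameterError("n_corrections must be in 0..3")
    rng = rng if rng is not None else np.random.default_rng(0)
    t0 = 0.2
    pulses = [(t0, d_main, mt_main)]
    onset = t0 + first_onset
    for _ in range(n_corrections):
        amp = float(rng.uniform(*correction_amplitude))
        dur = float(rng.uniform(*correction_duration))
        pulses.append((onset, amp, dur))
        onset += min_gap + float(rng.uniform(0.0, 0.02))
    t_end = max(p[0] + p[2] for p in pulses) + 0.25
    t = np.arange(0.0, t_end, 1.0 / fs)
    x = np.zeros_like(t)
    for start, amp, dur in pulses:
        x = x + minimum_jerk(amp, dur, t - start)
    if pos_noise_sd > 0:
        x = x + rng.normal(0.0, pos_noise_sd, size=x.shape)
    meta = {"injected_corrections": n_corrections, "kind": "composite",
            "phase": "synthetic"}
    return Trajectory(t, x, meta)
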