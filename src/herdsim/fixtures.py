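"""Synthetic-data generation: every analysis in the package is testable
without external data.

Three generators are provided:

* ``sample_initial_conditions`` — random trial configurations mimicking the
  pre-specified game initial conditions (agents anywhere on the field
  outside the containment zone, mutually separated, herder starting outside
  the target's influence radius);
* ``pseudo_human_cohort`` — a cohort of "participants" replaying one
  initial condition with jittered model parameters and smoothed positional
  noise, standing in for between-participant variability so the mean-
  trajectory / confidence-tube / trace machinery can be exercised;
* ``policy_labelled_logs`` — multi-target rollouts driven by a chosen
  target-selection policy, filtered for discriminability: across the
  returned set, every competing catalogue policy mispredicts at least one
  trial, so the generating policy is uniquely identifiable by the scorer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import Arena
from .herder_model import ModelParams, offset_goal
from .policies import (
    POLICY_CATALOGUE,
    IncompleteTrialError,
    PolicySpec,
    predict_order,
)
from .policy_scoring import observed_order
from .simulator import TrajectoryLog, TrialConfig, run_trial

__all__ = [
    "CohortSpec",
    "sample_initial_conditions",
    "pseudo_human_cohort",
    "policy_labelled_logs",
    "threshold_probe_trials",
]


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for a pseudo-human cohort."""

    n_participants: int = 12
    noise_sd: float = 1.0          # positional noise s.d. (m), smoothed
    param_jitter: float = 0.05     # multiplicative s.d. on model gains/decays
    noise_window_s: float = 0.5    # moving-average window of the noise (s)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.noise_sd < 0 or self.param_jitter < 0:
            raise ValueError("noise and jitter must be >= 0")


def _sample_positions(rng: np.random.Generator, n: int, arena: Arena,
                      min_sep: float, ha_ta_sep: float,
                      max_tries: int = 10_000) -> list[tuple[float, float]]:
    """Rejection-sample n points: in-field, off the zone, mutually separated.

    Index 0 is the herder; targets additionally keep ``ha_ta_sep`` from it so
    trials begin outside the influence radius, as in the game's
    pre-specified starts.
    """
    pts: list[tuple[float, float]] = []
    for _ in range(max_tries):
        p = (float(rng.uniform(-arena.half_width, arena.half_width)),
             float(rng.uniform(-arena.half_height, arena.half_height)))
        if math.hypot(*p) <= arena.containment_radius + 0.5:
            continue
        sep = ha_ta_sep if pts else 0.0
        ok = all(
            math.hypot(p[0] - q[0], p[1] - q[1]) >=
            (sep if i == 0 else min_sep)
            for i, q in enumerate(pts)
        )
        if ok:
            pts.append(p)
            if len(pts) == n + 1:
                return pts
    raise RuntimeError("could not sample a valid configuration")


def sample_initial_conditions(
    n: int,
    n_tas: int = 1,
    seed: int = 0,
    arena: Arena | None = None,
    policy: PolicySpec | None = None,
    min_separation: float = 2.0,
    ha_ta_separation: float = 12.0,
    heading: str = "random",
    **config_kw,
) -> list[TrialConfig]:
    """Reproducible random trial configurations.

    ``heading="random"`` draws the initial herder heading uniformly;
    ``heading="offset"`` points it at the first target's offset goal, giving
    transient-free starts (useful for parametrization references, where the
    start tangent of the path is fed back into the simulation).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if heading not in ("random", "offset"):
        raise ValueError("heading must be 'random' or 'offset'")
    arena = arena or Arena()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pts = _sample_positions(rng, n_tas, arena,
                                min_separation, ha_ta_separation)
        if heading == "offset":
            goal = offset_goal(pts[1], ModelParams().c_offset)
            h = math.degrees(math.atan2(goal[0] - pts[0][0],
                                        goal[1] - pts[0][1]))
        else:
            h = float(rng.uniform(-180.0, 180.0))
        out.append(TrialConfig(
            ha_position=pts[0],
            ha_heading_deg=h,
            ta_positions=tuple(pts[1:]),
            arena=arena,
            policy=policy,
            **config_kw,
        ))
    return out


def _smoothed_noise(rng: np.random.Generator, n: int, sd: float,
                    window: int) -> np.ndarray:
    """Moving-average-filtered Gaussian noise, rescaled back to s.d. ``sd``.

    Unfiltered white noise would produce kinematically impossible paths;
    the filter keeps the logs plausible at the sample rate while preserving
    the requested point-wise spread.
    """
    raw = rng.normal(0.0, sd, size=(n + window - 1, 2))
    kern = np.ones(window) / window
    sm = np.column_stack([np.convolve(raw[:, k], kern, mode="valid")
                          for k in (0, 1)])
    if sd > 0 and window > 1:
        sm *= math.sqrt(window)   # undo the variance reduction of the mean
    return sm


def pseudo_human_cohort(
    config: TrialConfig,
    spec: CohortSpec | None = None,
) -> list[TrajectoryLog]:
    """Cohort of jittered replays of one initial condition.

    Each "participant" gets model gains and decay constants multiplied by
    independent N(1, jitter) factors (clipped to stay positive) and smoothed
    additive positional noise on the herder path.  With zero jitter and zero
    noise every log equals the deterministic rollout.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    window = max(1, int(round(spec.noise_window_s / config.dt)))
    jittered = ("kg", "ko", "c1", "c2", "c3", "c4", "c5", "c6")
    logs = []
    for p in range(spec.n_participants):
        factors = np.clip(rng.normal(1.0, spec.param_jitter, len(jittered)),
                          0.2, None)
        mp = config.model.replace(
            **{k: getattr(config.model, k) * f
               for k, f in zip(jittered, factors)})
        log = run_trial(TrialConfig(
            ha_position=config.ha_position,
            ha_heading_deg=config.ha_heading_deg,
            ta_positions=config.ta_positions,
            arena=config.arena, model=mp, ta_params=config.ta_params,
            policy=config.policy, dt=config.dt,
            max_duration=config.max_duration,
            policy_period=config.policy_period,
            latch_mode=config.latch_mode, policy_mode=config.policy_mode,
        ))
        if spec.noise_sd > 0:
            noisy = log.ha + _smoothed_noise(
                rng, log.n_samples, spec.noise_sd, window)
            # recorded players never leave the fenced field
            arena = config.arena
            noisy[:, 0] = np.clip(noisy[:, 0], -arena.half_width,
                                  arena.half_width)
            noisy[:, 1] = np.clip(noisy[:, 1], -arena.half_height,
                                  arena.half_height)
            log.ha = noisy
        log.participant = f"p{p:02d}"
        logs.append(log)
    return logs


def policy_labelled_logs(
    policy: PolicySpec,
    n_trials: int = 6,
    seed: int = 0,
    n_tas: int = 3,
    competitors: dict[str, PolicySpec] | None = None,
    max_candidates: int = 120,
    arena: Arena | None = None,
) -> tuple[list[TrajectoryLog], list[list[int]]]:
    """Rollouts driven by ``policy`` whose generating policy is identifiable.

    Candidate configurations are sampled and simulated; a trial is kept only
    if the observed chase order equals the generating policy's prediction
    (accidental en-route influence of a non-target can break this).  Trials
    are accumulated until at least ``n_trials`` are kept *and* every
    competitor policy mispredicts at least one kept trial.  Raises if the
    candidate budget is exhausted first.
    """
    if competitors is None:
        competitors = {k: v for k, v in POLICY_CATALOGUE.items()
                       if v != policy}
    rng = np.random.default_rng(seed)
    uncovered = set(competitors)
    logs: list[TrajectoryLog] = []
    orders: list[list[int]] = []
    for _ in range(max_candidates):
        if len(logs) >= n_trials and not uncovered:
            break
        cfg = sample_initial_conditions(
            1, n_tas=n_tas, seed=int(rng.integers(2**31)),
            arena=arena, policy=policy)[0]
        log = run_trial(cfg)
        try:
            obs = observed_order(log)
            pred = predict_order(policy, log)
        except IncompleteTrialError:
            continue
        if obs != pred:
            continue
        newly = set()
        for name in uncovered:
            try:
                if predict_order(competitors[name], log) != obs:
                    newly.add(name)
            except IncompleteTrialError:
                newly.add(name)
        # keep the trial if we still need trials, or it covers a competitor
        if len(logs) < n_trials or newly:
            logs.append(log)
            orders.append(obs)
            uncovered -= newly
    if len(logs) < n_trials or uncovered:
        raise RuntimeError(
            f"discriminating configurations not found within budget "
            f"(kept {len(logs)}, uncovered competitors: {sorted(uncovered)})")
    return logs, orders


def threshold_probe_trials(
    tau_star: float,
    n_pairs: int = 4,
    seed: int = 0,
    angle_margin: float = 2.0,
    arena: Arena | None = None,
) -> list[TrajectoryLog]:
    """Trials that pin down the collinear-clustering threshold.

    Each trial places a target pair whose angle at the zone centre sits just
    below (``tau_star - angle_margin``) or just above
    (``tau_star + angle_margin``) the generating threshold, with the member
    angularly nearer the herder also nearer the zone (so clustering flips
    the selection order), plus a third, angularly remote target.  A sweep of
    the scoring threshold is then maximal at the grid point nearest
    ``tau_star``.
    """
    arena = arena or Arena()
    rng = np.random.default_rng(seed)
    sca = POLICY_CATALOGUE["successive_collinear_angle"]
    gen = sca.with_threshold(tau_star)
    logs = []
    attempts = 0
    want = [tau_star - angle_margin, tau_star + angle_margin] * n_pairs
    for pair_angle in want:
        while True:
            attempts += 1
            if attempts > 400:
                raise RuntimeError("could not build threshold-probe trials")
            base = float(rng.uniform(-180.0, 180.0))
            b_near = math.radians(base)
            b_far = math.radians(base + pair_angle)
            r_near = float(rng.uniform(18.0, 24.0))
            r_far = float(rng.uniform(32.0, 40.0))
            near = (r_near * math.sin(b_near), r_near * math.cos(b_near))
            far = (r_far * math.sin(b_far), r_far * math.cos(b_far))
            b3 = math.radians(base + float(rng.uniform(70.0, 110.0)))
            r3 = float(rng.uniform(20.0, 35.0))
            third = (r3 * math.sin(b3), r3 * math.cos(b3))
            bh = math.radians(base - float(rng.uniform(25.0, 40.0)))
            rh = float(rng.uniform(30.0, 40.0))
            ha = (rh * math.sin(bh), rh * math.cos(bh))
            if not all(arena.contains(p) for p in (near, far, third, ha)):
                continue
            try:
                cfg = TrialConfig(ha, math.degrees(bh), (near, far, third),
                                  arena=arena, policy=gen)
                log = run_trial(cfg)
                if observed_order(log) == predict_order(gen, log):
                    logs.append(log)
                    break
            except (ValueError, IncompleteTrialError):
                continue
    return logs
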