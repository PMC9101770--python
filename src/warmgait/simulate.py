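"""Synthetic annotated hip-rotation trials.

Generates unit-quaternion time series that emulate a scripted indoor walking
course: alternating walking activities (straight line, curved line, stairs)
and non-walking activities (3-second pauses, sit-down/stand-up holds), sampled
at 100 Hz for about 90 s per trial.

During walking the hip orientation is the composition of

* a slow orientation drift about a fixed random axis (sensor-fusion and
  posture drift),
* a sinusoidal sway at the cadence frequency about a body axis — the
  periodic hip rotation of gait — whose amplitude is ramped on/off with a
  short raised-cosine envelope at phase edges so starts and stops are not
  single-sample discontinuities, and
* small per-sample jitter rotations (sensor noise), composed
  multiplicatively so the series stays on the unit sphere.

During pauses and sit/stand holds only drift and jitter act.  Every sample is
labelled 1 iff its scheduled activity is a walking kind, with ground-truth
change points exactly at schedule boundaries.

This is deliberately *not* a biomechanical gait model: it produces the
signal structure the feature transforms rely on (sustained rotation rate
during walking, quasi-static orientation otherwise), not realistic kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import quaternions as quat
from .features import UQTSTrial

__all__ = [
    "WALKING_KINDS",
    "TrialRecipe",
    "default_schedule",
    "simulate_trial",
    "simulate_dataset",
]

#: Activity kinds whose samples are labelled as walking.
WALKING_KINDS = frozenset({"straight_walk", "curved_walk", "stairs"})

#: All recognised activity kinds.
ACTIVITY_KINDS = WALKING_KINDS | {"sit_stand", "pause"}


def default_schedule(pause_duration: float = 3.0) -> list[tuple[str, float]]:
    """The default ~90 s course: walking bouts and holds separated by pauses.

    Walking occupies 41 s of the 90 s total, a walking prevalence of ≈0.456.
    """
    p = float(pause_duration)
    return [
        ("straight_walk", 8.0),
        ("pause", p),
        ("curved_walk", 7.0),
        ("pause", p),
        ("stairs", 6.0),
        ("pause", p),
        ("sit_stand", 14.0),
        ("pause", p),
        ("stairs", 6.0),
        ("pause", p),
        ("curved_walk", 7.0),
        ("pause", p),
        ("sit_stand", 14.0),
        ("pause", p),
        ("straight_walk", 7.0),
    ]


@dataclass
class TrialRecipe:
    """Generation parameters for one synthetic trial.

    Parameters
    ----------
    sample_rate
        Hz (default 100).
    activity_schedule
        Ordered (kind, duration-seconds) pairs; defaults to
        :func:`default_schedule`.
    cadence
        Steps per second during walking (default 1.8: a brisk indoor pace).
    sway_amplitude
        Radians of periodic hip oscillation during walking (default 0.15).
    jitter_sd
        Radians of small-angle orientation noise per sample (default 0.002).
    drift_rate
        Radians/second of slow orientation drift (default 0.01).
    """

    sample_rate: float = 100.0
    activity_schedule: Sequence[tuple[str, float]] = field(default_factory=default_schedule)
    pause_duration: float = 3.0
    cadence: float = 1.8
    sway_amplitude: float = 0.15
    jitter_sd: float = 0.002
    drift_rate: float = 0.01
    ramp_duration: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.activity_schedule:
            raise ValueError("activity_schedule must not be empty")
        for kind, dur in self.activity_schedule:
            if kind not in ACTIVITY_KINDS:
                raise ValueError(f"unknown activity kind {kind!r}")
            if dur <= 0:
                raise ValueError("activity durations must be positive")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        for name in ("sway_amplitude", "jitter_sd", "drift_rate", "ramp_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def preset(cls, name: str, **overrides) -> "TrialRecipe":
        """Named difficulty presets: ``easy`` (defaults) and ``hard``
        (5× jitter, half the sway amplitude)."""
        if name == "easy":
            return cls(**overrides)
        if name == "hard":
            base = cls(**overrides)
            return replace(
                base, jitter_sd=base.jitter_sd * 5.0, sway_amplitude=base.sway_amplitude * 0.5
            )
        raise ValueError(f"unknown preset {name!r} (expected 'easy' or 'hard')")


def _quats_from_rotvecs(v: np.ndarray) -> np.ndarray:
    """Axis-angle rotation vectors (N, 3) → unit quaternions (N, 4)."""
    angle = np.linalg.norm(v, axis=-1)
    half = 0.5 * angle
    w = np.cos(half)
    # sin(θ/2)/θ, with the θ→0 limit 1/2
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(angle > 1e-12, np.sin(half) / np.where(angle > 0, angle, 1.0), 0.5)
    return np.concatenate([w[..., None], v * s[..., None]], axis=-1)


# body axes for the sway oscillation: straight walking rocks about one axis,
# curved walking and stairs about another, for mild feature-space diversity
_AXIS_BY_KIND = {
    "straight_walk": np.array([1.0, 0.0, 0.0]),
    "curved_walk": np.array([0.0, 1.0, 0.0]),
    "stairs": np.array([0.0, 1.0, 0.0]),
}


def simulate_trial(recipe: TrialRecipe) -> UQTSTrial:
    """Generate one annotated trial; deterministic given ``recipe.seed``."""
    rng = np.random.default_rng(recipe.seed)
    dt = 1.0 / recipe.sample_rate

    # per-sample activity kind
    counts = [int(round(dur * recipe.sample_rate)) for _, dur in recipe.activity_schedule]
    kinds: list[str] = []
    for (kind, _), n in zip(recipe.activity_schedule, counts):
        kinds.extend([kind] * n)
    n_samples = len(kinds)
    t = np.arange(n_samples) * dt
    labels = np.fromiter((k in WALKING_KINDS for k in kinds), dtype=int, count=n_samples)

    # sway angle: sinusoid at cadence frequency, restarted and enveloped per
    # walking segment
    sway = np.zeros(n_samples)
    axis = np.zeros((n_samples, 3))
    start = 0
    for (kind, _), n in zip(recipe.activity_schedule, counts):
        stop = start + n
        if kind in WALKING_KINDS and n > 0:
            local_t = np.arange(n) * dt
            envelope = np.ones(n)
            n_ramp = min(int(round(recipe.ramp_duration * recipe.sample_rate)), n // 2)
            if n_ramp > 0:
                ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
                envelope[:n_ramp] = ramp
                envelope[n - n_ramp :] = ramp[::-1]
            sway[start:stop] = (
                recipe.sway_amplitude
                * envelope
                * np.sin(2.0 * np.pi * recipe.cadence * local_t)
            )
            axis[start:stop] = _AXIS_BY_KIND[kind]
        start = stop

    q_sway = _quats_from_rotvecs(axis * sway[:, None])

    # slow drift about a fixed random axis
    drift_axis = rng.normal(size=3)
    drift_axis /= np.linalg.norm(drift_axis)
    q_drift = _quats_from_rotvecs(drift_axis[None, :] * (recipe.drift_rate * t)[:, None])

    # per-sample jitter: small random rotations composed multiplicatively
    jitter_vec = rng.normal(scale=recipe.jitter_sd, size=(n_samples, 3))
    q_jitter = _quats_from_rotvecs(jitter_vec)

    q = quat.hamilton_product(quat.hamilton_product(q_drift, q_sway), q_jitter)
    q /= np.linalg.norm(q, axis=-1, keepdims=True)

    return UQTSTrial(times=t, quaternions=q, labels=labels)


def simulate_dataset(
    n_trials: int,
    n_subjects: int,
    recipe_template: Optional[TrialRecipe] = None,
    seed: int = 0,
) -> list[UQTSTrial]:
    """Generate a dataset of trials over subjects assigned round-robin.

    Each subject gets a fixed random perturbation (±10%) of cadence and sway
    amplitude, emulating between-subject gait variation; per-trial noise seeds
    are spawned deterministically from ``seed``.
    """
    if n_subjects < 1 or n_trials < n_subjects:
        raise ValueError("need n_trials ≥ n_subjects ≥ 1")
    template = recipe_template if recipe_template is not None else TrialRecipe()

    root = np.random.SeedSequence(seed)
    subject_rng = np.random.default_rng(root.spawn(1)[0])
    cadence_factors = subject_rng.uniform(0.9, 1.1, size=n_subjects)
    amp_factors = subject_rng.uniform(0.9, 1.1, size=n_subjects)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_trials)]

    trials = []
    for i in range(n_trials):
        subj = i % n_subjects
        recipe = replace(
            template,
            cadence=template.cadence * cadence_factors[subj],
            sway_amplitude=template.sway_amplitude * amp_factors[subj],
            seed=trial_seeds[i],
        )
        trial = simulate_trial(recipe)
        trial.trial_id = f"trial{i:03d}"
        trial.subject_id = f"S{subj + 1}"
        trials.append(trial)
    return trials
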