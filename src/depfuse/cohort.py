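"""Synthetic multimodal cohort generator.

Emulates the structure of the mood-elicitation study the pipeline targets:
each subject completes 5 stimulus tasks x 3 emotional valences (15
sessions), every session yielding a time-aligned stream of RGB face
crops, 1,347-point 3-D facial landmarks with 17 AU intensities, and SAM
valence/arousal ratings before and after the stimulus.

The class signal is controlled by a single ``effect_size`` knob and is
injected in two complementary places:

* **dynamics** (3D stream): the expression-state trajectory of depressed
  subjects is blunted under positive and negative stimuli — amplitude
  scaled by 1/(1 + 0.6 e), short-time variability by 1/(1 + 0.3 e), plus a
  mild negative drift — while neutral sessions are nearly identical across
  groups;
* **static appearance** (2D stream): the subject-level baseline mouth
  curvature of the depressed group is shifted down by 0.2 e against a
  between-subject SD of 0.2.

SAM rating deltas follow the qualitative clinical pattern: healthy shifts
track the stimulus valence, depressed shifts are non-positive under both
positive and negative stimuli, and arousal responses are larger for the
healthy group; all class differences vanish at ``effect_size = 0``.

Everything is driven by ``numpy`` Philox/PCG streams seeded per subject
and session, so cohorts are bit-identical across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import (
    N_AUS,
    N_LANDMARKS,
    TASKS,
    VALENCES,
    LandmarkFrame,
    Session,
    subsample_frames,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_face_frame",
    "generate_landmark_sequence",
    "generate_sam_ratings",
    "generate_sam_frame",
    "landmark_template",
]

_VSIGN = {"positive": 1.0, "neutral": 0.0, "negative": -1.0}
_TASK_GAIN = {
    "film": 1.5,
    "expression_picture": 1.1,
    "question": 0.9,
    "reading": 0.8,
    "scene_picture": 0.8,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped cohort parameters.

    Cells are gender x group; the default balanced design mirrors the
    52-per-cell study layout at reduced size. ``frames_per_session`` is
    the raw recording length; with ``materialize="subsampled"`` only the
    one-in-``interval`` frames that survive subsampling are stored (the
    state trajectory is still simulated at the raw rate).
    """

    n_subjects_per_cell: int = 10
    effect_size: float = 1.0
    frames_per_session: int = 3000
    interval: int = 100
    image_size: int = 100
    seed: int = 0
    materialize: str = "subsampled"
    landmark_jitter: float = 8e-4

    def __post_init__(self) -> None:
        if self.n_subjects_per_cell < 1 or self.frames_per_session < 1:
            raise ConfigurationError("subject and frame counts must be positive")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be nonnegative")
        if self.materialize not in ("subsampled", "dense"):
            raise ConfigurationError("materialize must be 'subsampled' or 'dense'")

    @classmethod
    def tiny(cls, **kw) -> "CohortSpec":
        return cls(**{**dict(n_subjects_per_cell=2, frames_per_session=30, interval=10, image_size=16), **kw})

    @classmethod
    def desk(cls, **kw) -> "CohortSpec":
        # interval 30 keeps ten stored frames per session so the sequence
        # model sees an actual trajectory at workstation scale
        return cls(**{**dict(n_subjects_per_cell=10, frames_per_session=300, interval=30, image_size=32), **kw})

    @classmethod
    def paper_shape(cls, **kw) -> "CohortSpec":
        return cls(**{**dict(n_subjects_per_cell=52, frames_per_session=3000, interval=100, image_size=100), **kw})


# ---------------------------------------------------------------------------
# face images


def generate_face_frame(
    state: float,
    rng: np.random.Generator,
    size: int = 100,
    appearance: float = 0.0,
) -> np.ndarray:
    """Parametric face crop: oval, eyes, and a mouth whose curvature is
    strictly increasing in ``appearance + 0.5 * state``; uint8 RGB."""
    h = w = size
    img = np.empty((h, w, 3), dtype=float)
    img[:] = (150.0, 150.0, 155.0)  # background
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = 0.5 * h, 0.5 * w
    face = ((yy - cy) / (0.46 * h)) ** 2 + ((xx - cx) / (0.36 * w)) ** 2 <= 1.0
    img[face] = (225.0, 195.0, 170.0)  # skin
    for ex in (0.36 * w, 0.64 * w):
        eye = ((yy - 0.38 * h) / (0.035 * h)) ** 2 + ((xx - ex) / (0.07 * w)) ** 2 <= 1.0
        img[eye] = (55.0, 45.0, 45.0)
    curv = float(np.clip(appearance + 0.5 * state, -1.3, 1.3))
    half = 0.18 * w
    thickness = max(1, h // 33)
    for x in range(int(cx - half), int(cx + half) + 1):
        u = (x - cx) / half
        row = 0.70 * h + curv * (u * u - 0.5) * 0.10 * h
        r0 = int(round(row))
        img[max(r0, 0) : min(r0 + thickness, h), x] = (160.0, 60.0, 60.0)
    img += rng.uniform(-8.0, 8.0, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# landmarks and AUs

_template_cache: dict[int, np.ndarray] = {}


def landmark_template(n: int = N_LANDMARKS) -> np.ndarray:
    """Fixed face-shaped point cloud: Fibonacci lattice on a half-ellipsoid.

    Units are meters at a typical Kinect working distance; x spans the face
    width, y its height, z depth relief.
    """
    if n not in _template_cache:
        k = np.arange(n)
        golden = (1.0 + math.sqrt(5.0)) / 2.0
        theta = 2.0 * math.pi * k / golden
        # front hemisphere only: cos(phi) in [0, 1]
        cos_phi = k / (n - 1.0)
        sin_phi = np.sqrt(1.0 - cos_phi**2)
        x = 0.075 * sin_phi * np.cos(theta)
        y = 0.105 * sin_phi * np.sin(theta)
        z = 0.060 * cos_phi
        _template_cache[n] = np.column_stack([x, y, z])
    return _template_cache[n]


def _deformation_modes(template: np.ndarray) -> np.ndarray:
    """Two expression modes: mouth-corner lift and brow raise, (2, n, 3)."""
    x, y = template[:, 0], template[:, 1]
    mouth = (y < -0.045) & (np.abs(x) < 0.05)
    brow = (y > 0.055) & (np.abs(x) < 0.06)
    m1 = np.zeros_like(template)
    m1[mouth, 1] = 0.012 * (x[mouth] / 0.05) ** 2 - 0.004  # corners up, center down
    m1[mouth, 2] = 0.004
    m2 = np.zeros_like(template)
    m2[brow, 1] = 0.006
    return np.stack([m1, m2])


def generate_landmark_sequence(
    states: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 8e-4,
    frame_indices: np.ndarray | None = None,
) -> list[LandmarkFrame]:
    """Landmark/AU frames for a state trajectory.

    Each frame is the fixed template plus expression modes scaled by the
    state plus Gaussian sensor jitter; the 17 AU channels are fixed
    per-channel affine responses to the state, clipped to [-1, 1].
    """
    states = np.asarray(states, dtype=float)
    template = landmark_template()
    modes = _deformation_modes(template)
    if frame_indices is None:
        frame_indices = np.arange(states.size)
    ks = np.arange(1, N_AUS + 1)
    au_lin = 0.8 * np.cos(ks)  # signed response
    au_abs = 0.25 * np.abs(np.sin(2.0 * ks))  # magnitude response
    frames = []
    for s, fi in zip(states, frame_indices):
        pts = template + s * modes[0] + 0.6 * s * modes[1]
        if jitter > 0:
            pts = pts + rng.normal(0.0, jitter, size=pts.shape)
        aus = au_lin * s + au_abs * abs(s)
        if jitter > 0:
            aus = aus + rng.normal(0.0, 0.05, size=N_AUS)
        frames.append(
            LandmarkFrame(
                frame_index=int(fi),
                points=pts,
                aus=np.clip(aus, -1.0, 1.0),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# SAM ratings


def generate_sam_ratings(
    label: int,
    task: str,
    valence: str,
    rng: np.random.Generator,
    effect_size: float = 1.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(pre, post) SAM (valence, arousal) ratings on the 1-9 scale.

    Healthy post-pre valence shifts carry the stimulus sign; depressed
    shifts are blunted and non-positive under both positive and negative
    stimuli, with smaller arousal responses. The group contrast scales
    with ``effect_size`` and vanishes at 0.
    """
    gain = _TASK_GAIN[task]
    v = _VSIGN[valence]
    w = float(np.clip(effect_size, 0.0, 1.0)) if label else 0.0
    healthy_dv = gain * v
    healthy_da = 0.7 * gain * abs(v) + 0.05
    dv_mean = (1.0 - w) * healthy_dv + w * (-0.6 * gain * abs(v))
    da_mean = (1.0 - w) * healthy_da + w * 0.05
    pre_v = float(np.clip(np.rint(rng.normal(5.0 - 0.7 * w, 1.2)), 1, 9))
    pre_a = float(np.clip(np.rint(rng.normal(4.5, 1.2)), 1, 9))
    post_v = float(np.clip(np.rint(pre_v + dv_mean + rng.normal(0.0, 1.0)), 1, 9))
    post_a = float(np.clip(np.rint(pre_a + da_mean + rng.normal(0.0, 1.0)), 1, 9))
    return (pre_v, pre_a), (post_v, post_a)


# ---------------------------------------------------------------------------
# cohort assembly


def _state_trajectory(
    n_frames: int,
    label: int,
    valence: str,
    effect_size: float,
    gain: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw-rate expression-state trajectory in [-1, 1]-ish units."""
    t = np.arange(n_frames)
    v = _VSIGN[valence]
    if v == 0.0:
        amp = 0.12 * gain  # neutral: both groups respond alike
        drift = 0.0
    else:
        blunt = 1.0 / (1.0 + 0.6 * effect_size) if label else 1.0
        amp = 0.9 * v * gain * blunt
        drift = -0.10 * min(effect_size, 2.0) if label else 0.0
    env = np.sin(np.pi * (t + 0.5) / n_frames)
    sd = 0.12
    if label and v != 0.0:
        sd = sd / (1.0 + 0.3 * effect_size)
    rho = 0.95
    noise = np.empty(n_frames)
    x = rng.normal(0.0, sd)
    scale = math.sqrt(1.0 - rho**2) * sd
    for i in range(n_frames):
        noise[i] = x
        x = rho * x + rng.normal(0.0, scale)
    return amp * env + drift + noise


def _make_session(
    spec: CohortSpec,
    subject_id: str,
    label: int,
    gender: str,
    phq9: int,
    gain: float,
    appearance: float,
    task: str,
    valence: str,
    rng: np.random.Generator,
) -> Session:
    states = _state_trajectory(
        spec.frames_per_session, label, valence, spec.effect_size, gain, rng
    )
    if spec.materialize == "subsampled":
        idx = subsample_frames(spec.frames_per_session, spec.interval)
    else:
        idx = np.arange(spec.frames_per_session)
    frames_3d = generate_landmark_sequence(
        states[idx], rng, jitter=spec.landmark_jitter, frame_indices=idx
    )
    frames_rgb = np.stack(
        [
            generate_face_frame(states[i], rng, size=spec.image_size, appearance=appearance)
            for i in idx
        ]
    )
    sam_pre, sam_post = generate_sam_ratings(
        label, task, valence, rng, effect_size=spec.effect_size
    )
    return Session(
        subject_id=subject_id,
        task=task,
        valence=valence,
        label=label,
        gender=gender,
        phq9=phq9,
        frames_rgb=frames_rgb,
        frames_3d=frames_3d,
        sam_pre=sam_pre,
        sam_post=sam_post,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[Session], dict]:
    """Generate the full balanced cohort.

    Returns (sessions, manifest); sessions are ordered by subject, task,
    valence and the manifest records per-subject metadata plus the spec.
    """
    sessions: list[Session] = []
    manifest: dict = {"spec": asdict(spec), "subjects": {}}
    subj_idx = 0
    for label in (0, 1):
        for gender in ("male", "female"):
            for _ in range(spec.n_subjects_per_cell):
                srng = np.random.default_rng([spec.seed, 7919, subj_idx])
                subject_id = f"S{subj_idx:04d}"
                phq9 = int(srng.integers(0, 5)) if label == 0 else int(srng.integers(5, 28))
                gain = max(0.05, 1.0 + srng.normal(0.0, 0.12))
                appearance = srng.normal(
                    0.10 - 0.20 * spec.effect_size * label, 0.20
                )
                manifest["subjects"][subject_id] = {
                    "label": label,
                    "gender": gender,
                    "phq9": phq9,
                    "sessions": [],
                }
                for ti, task in enumerate(TASKS):
                    for vi, valence in enumerate(VALENCES):
                        rng = np.random.default_rng([spec.seed, subj_idx, ti, vi])
                        sessions.append(
                            _make_session(
                                spec, subject_id, label, gender, phq9,
                                gain, appearance, task, valence, rng,
                            )
                        )
                        manifest["subjects"][subject_id]["sessions"].append(
                            f"{task}_{valence}"
                        )
                subj_idx += 1
    return sessions, manifest


def generate_sam_frame(spec: CohortSpec) -> pd.DataFrame:
    """SAM rating deltas only (no image/landmark synthesis) — one row per
    subject x task x valence, for fast calibration studies."""
    rows = []
    subj_idx = 0
    for label in (0, 1):
        for gender in ("male", "female"):
            for _ in range(spec.n_subjects_per_cell):
                subject_id = f"S{subj_idx:04d}"
                for ti, task in enumerate(TASKS):
                    for vi, valence in enumerate(VALENCES):
                        rng = np.random.default_rng([spec.seed, 104729, subj_idx, ti, vi])
                        pre, post = generate_sam_ratings(
                            label, task, valence, rng, effect_size=spec.effect_size
                        )
                        rows.append(
                            {
                                "subject_id": subject_id,
                                "label": label,
                                "gender": gender,
                                "task": task,
                                "valence": valence,
                                "d_valence": post[0] - pre[0],
                                "d_arousal": post[1] - pre[1],
                            }
                        )
                subj_idx += 1
    return pd.DataFrame(rows)
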