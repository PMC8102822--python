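"""Session data layout, readers/writers and the preprocessing chain.

A recording session is one subject x stimulus task x emotional valence. On
disk a session is a directory:

    session.json            metadata, label, SAM pre/post ratings
    landmarks.csv           frame_index, x_0001, y_0001, z_0001, ..., z_1347
    aus.csv                 frame_index, AU01, ..., AU17
    frames/frame_00000.png  100 x 100 RGB face crops (one per stored frame)

Landmark indices are 1-based in file headers and 0-based in memory.

The preprocessing chain mirrors the recording pipeline: subsample one frame
every 100, split images into R/G/B channel vectors scaled to [0, 1], and
z-score each landmark frame per coordinate set (all x of frame t together,
likewise y, z and the AU block) before concatenating into the
3 * 1347 (+17) frame vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DegenerateFrameError, InvalidInputError, SessionFormatError

__all__ = [
    "LandmarkFrame",
    "Session",
    "TASKS",
    "VALENCES",
    "subsample_frames",
    "image_to_channel_vectors",
    "zscore_frame",
    "normalize_landmark_frame",
    "frame_to_vector",
    "session_to_features",
    "read_session",
    "write_session",
    "write_cohort",
    "read_cohort",
]

TASKS = ("film", "question", "reading", "scene_picture", "expression_picture")
VALENCES = ("positive", "neutral", "negative")

N_LANDMARKS = 1347
N_AUS = 17


@dataclass(frozen=True)
class LandmarkFrame:
    """One Kinect frame: 1,347 3-D facial points and 17 AU intensities in [-1, 1]."""

    frame_index: int
    points: np.ndarray
    aus: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        aus = np.asarray(self.aus, dtype=float)
        if pts.shape != (N_LANDMARKS, 3):
            raise InvalidInputError(
                f"landmark frame must hold {N_LANDMARKS} (x,y,z) points, got {pts.shape}"
            )
        if aus.shape != (N_AUS,):
            raise InvalidInputError(f"expected {N_AUS} AU intensities, got {aus.shape}")
        if np.any(np.abs(aus) > 1.0 + 1e-12):
            raise InvalidInputError("AU intensities must lie within [-1, 1]")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "aus", aus)


@dataclass
class Session:
    """One aligned multimodal recording (images + landmarks/AUs + ratings)."""

    subject_id: str
    task: str
    valence: str
    label: int
    gender: str
    phq9: int
    frames_rgb: np.ndarray  # (T, H, W, 3) uint8
    frames_3d: list[LandmarkFrame]
    sam_pre: tuple[float, float]  # (valence 1-9, arousal 1-9)
    sam_post: tuple[float, float]

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise InvalidInputError(f"unknown task {self.task!r}")
        if self.valence not in VALENCES:
            raise InvalidInputError(f"unknown valence {self.valence!r}")
        if len(self.frames_rgb) != len(self.frames_3d):
            raise InvalidInputError("image and 3D streams are not time-aligned")


def subsample_frames(n_frames: int, interval: int = 100) -> np.ndarray:
    """Indices {0, interval, 2*interval, ...} < n_frames."""
    if n_frames < 1 or interval < 1:
        raise InvalidInputError("n_frames and interval must be >= 1")
    return np.arange(0, n_frames, interval)


def image_to_channel_vectors(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB frame into three row-major flattened vectors in [0, 1]."""
    img = np.asarray(frame)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
        raise SessionFormatError(f"expected a square (H, H, 3) image, got {img.shape}")
    flat = img.astype(float) / 255.0
    return tuple(flat[:, :, c].ravel(order="C") for c in range(3))


def zscore_frame(values: np.ndarray) -> np.ndarray:
    """Standardize one coordinate set with the population (divisor-N) SD."""
    x = np.asarray(values, dtype=float)
    mu = x.mean()
    sd = x.std()
    if sd == 0.0:
        raise DegenerateFrameError("constant coordinate set cannot be standardized")
    return (x - mu) / sd


def normalize_landmark_frame(frame: LandmarkFrame) -> tuple[np.ndarray, np.ndarray]:
    """Z-score x, y, z coordinate sets and the AU block of one frame.

    Returns (points (1347, 3), aus (17,)), each standardized to zero mean
    and unit population SD within the frame.
    """
    pts = np.column_stack([zscore_frame(frame.points[:, k]) for k in range(3)])
    return pts, zscore_frame(frame.aus)


def frame_to_vector(frame: LandmarkFrame, include_au: bool = False) -> np.ndarray:
    """Normalized frame vector [x1, y1, z1, ..., xn, yn, zn (, AU1..AU17)].

    Length 4041 without AUs, 4058 with (coordinates interleaved per point).
    """
    pts, aus = normalize_landmark_frame(frame)
    vec = pts.ravel(order="C")
    if include_au:
        vec = np.concatenate([vec, aus])
    return vec


def session_to_features(
    session: Session,
    interval: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model-ready arrays for one session.

    Returns (channels (3, T, H*H), frames3d (T, 4041), aus (T, 17)) after
    subsampling stored frames with ``interval`` (stored frames are usually
    already subsampled, hence the default of 1).
    """
    idx = subsample_frames(len(session.frames_3d), interval)
    chans = []
    f3, au = [], []
    for i in idx:
        chans.append(image_to_channel_vectors(session.frames_rgb[i]))
        pts, aus_n = normalize_landmark_frame(session.frames_3d[i])
        f3.append(pts.ravel(order="C"))
        au.append(aus_n)
    channels = np.stack([np.stack([c[ch] for c in chans]) for ch in range(3)])
    return channels, np.asarray(f3), np.asarray(au)


# ---------------------------------------------------------------------------
# on-disk layout


def _landmark_columns() -> list[str]:
    cols = []
    for i in range(1, N_LANDMARKS + 1):
        cols += [f"x_{i:04d}", f"y_{i:04d}", f"z_{i:04d}"]
    return cols


def _au_columns() -> list[str]:
    return [f"AU{k:02d}" for k in range(1, N_AUS + 1)]


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session directory (PNG frames, CSV streams, JSON sidecar)."""
    path = Path(path)
    (path / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    au_rows = []
    for fr in session.frames_3d:
        rows.append([fr.frame_index] + fr.points.ravel(order="C").tolist())
        au_rows.append([fr.frame_index] + fr.aus.tolist())
    pd.DataFrame(rows, columns=["frame_index"] + _landmark_columns()).to_csv(
        path / "landmarks.csv", index=False
    )
    pd.DataFrame(au_rows, columns=["frame_index"] + _au_columns()).to_csv(
        path / "aus.csv", index=False
    )
    for i, img in enumerate(session.frames_rgb):
        iio.imwrite(path / "frames" / f"frame_{i:05d}.png", np.asarray(img, dtype=np.uint8))
    meta = {
        "subject_id": session.subject_id,
        "task": session.task,
        "valence": session.valence,
        "label": int(session.label),
        "gender": session.gender,
        "phq9": int(session.phq9),
        "sam_pre": list(map(float, session.sam_pre)),
        "sam_post": list(map(float, session.sam_post)),
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> Session:
    """Read a session directory; validates layout, column counts and AU range."""
    path = Path(path)
    for fname in ("session.json", "landmarks.csv", "aus.csv"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing stream: {fname} in {path}")
    if not (path / "frames").is_dir():
        raise SessionFormatError(f"missing stream: frames/ in {path}")
    meta = json.loads((path / "session.json").read_text())
    lm = pd.read_csv(path / "landmarks.csv")
    if lm.shape[1] != 1 + 3 * N_LANDMARKS:
        raise SessionFormatError(
            f"landmarks.csv has {lm.shape[1]} columns, expected {1 + 3 * N_LANDMARKS}"
        )
    au = pd.read_csv(path / "aus.csv")
    if au.shape[1] != 1 + N_AUS:
        raise SessionFormatError(
            f"aus.csv has {au.shape[1]} columns, expected {1 + N_AUS}"
        )
    au_vals = au.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(np.abs(au_vals) > 1.0 + 1e-12):
        raise SessionFormatError("AU intensity outside [-1, 1] in aus.csv")
    if lm.shape[0] != au.shape[0]:
        raise SessionFormatError("landmark and AU streams differ in frame count")
    frames_3d = [
        LandmarkFrame(
            frame_index=int(lm.iloc[t, 0]),
            points=lm.iloc[t, 1:].to_numpy(dtype=float).reshape(N_LANDMARKS, 3),
            aus=au_vals[t],
        )
        for t in range(lm.shape[0])
    ]
    frame_files = sorted((path / "frames").glob("frame_*.png"))
    if len(frame_files) != len(frames_3d):
        raise SessionFormatError(
            f"{len(frame_files)} image frames vs {len(frames_3d)} 3D frames"
        )
    frames_rgb = np.stack([iio.imread(f) for f in frame_files])
    return Session(
        subject_id=meta["subject_id"],
        task=meta["task"],
        valence=meta["valence"],
        label=int(meta["label"]),
        gender=meta["gender"],
        phq9=int(meta["phq9"]),
        frames_rgb=frames_rgb,
        frames_3d=frames_3d,
        sam_pre=tuple(meta["sam_pre"]),
        sam_post=tuple(meta["sam_post"]),
    )


def write_cohort(sessions: list[Session], root: str | Path) -> Path:
    """Write all sessions plus a manifest.json mapping subjects to sessions."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for sess in sessions:
        rel = f"{sess.subject_id}/{sess.task}_{sess.valence}"
        write_session(sess, root / rel)
        manifest.setdefault(sess.subject_id, []).append(rel)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root


def read_cohort(root: str | Path) -> list[Session]:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    return [
        read_session(root / rel) for subject in sorted(manifest) for rel in manifest[subject]
    ]
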