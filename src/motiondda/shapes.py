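"""Parametric template trajectories for the six motion classes.

The VR collection protocol records six hand-drawn shapes ("Cube", "Cylinder",
"Heart", "Infinity", "Sphere", "Triangle") as planar trajectories resampled to
32 points.  This module generates seedable synthetic stand-ins for those
recordings: parametric template curves with per-trial jitter, an arc-length
uniform resampler, and an emulator of the full collection protocol
(participants x labels x repetitions x sessions).

Conventions: every template is centred at its point centroid and scaled so the
larger bounding-box side equals 1; jitter and noise magnitudes are expressed
as fractions of the bounding-box diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The six permitted motion classes, in canonical (alphabetical) order.
LABELS: tuple[str, ...] = ("Cube", "Cylinder", "Heart", "Infinity", "Sphere", "Triangle")

#: Number of points every motion matrix is resampled to.
N_POINTS: int = 32


@dataclass
class MotionMatrix:
    """One recorded (or synthesised) motion: a 32x2 matrix plus a class label.

    Parameters
    ----------
    points
        Array of shape (32, 2) with finite planar coordinates.
    label
        One of :data:`LABELS`.
    meta
        Optional provenance indices (participant, session, repetition).
    """

    points: np.ndarray
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_POINTS, 2):
            raise ValueError(
                f"motion matrix must have shape ({N_POINTS}, 2), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("motion matrix contains non-finite coordinates")
        if self.label not in LABELS:
            raise ValueError(f"unknown motion label {self.label!r}; expected one of {LABELS}")

    def flattened(self) -> np.ndarray:
        """Row-major flattening into the 64-value network input vector."""
        return self.points.reshape(-1)


@dataclass
class ProtocolSpec:
    """Collection-protocol dimensions: 10 participants x 6 motions x 3 reps x 3 sessions."""

    n_participants: int = 10
    n_labels: int = 6
    reps_per_session: int = 3
    n_sessions: int = 3
    participant_jitter: float = 0.05
    trial_jitter: float = 0.02
    n_raw_points: int = 64

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_labels", "reps_per_session", "n_sessions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 1 <= self.n_labels <= len(LABELS):
            raise ValueError(f"n_labels must be in [1, {len(LABELS)}]")

    @property
    def total_motions(self) -> int:
        return self.n_participants * self.n_labels * self.reps_per_session * self.n_sessions


def _raw_template(label: str, n: int) -> np.ndarray:
    """Un-normalised parametric curve for one shape class, n points."""
    if label == "Sphere":  # circle
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return 0.5 * np.column_stack([np.cos(t), np.sin(t)])
    if label == "Infinity":  # figure-eight, self-crossing at the origin
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack([np.cos(t), 0.5 * np.sin(2.0 * t)])
    if label == "Heart":
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        x = 16.0 * np.sin(t) ** 3
        y = 13.0 * np.cos(t) - 5.0 * np.cos(2 * t) - 2.0 * np.cos(3 * t) - np.cos(4 * t)
        return np.column_stack([x, y]) / 17.0
    if label == "Cube":  # unit square traced from the bottom-left corner
        return _polygon_perimeter(
            np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]]), n
        )
    if label == "Cylinder":  # rectangle, aspect 1:2 (frontal silhouette)
        return _polygon_perimeter(
            np.array([[-0.25, -0.5], [0.25, -0.5], [0.25, 0.5], [-0.25, 0.5]]), n
        )
    if label == "Triangle":  # equilateral, apex up
        angles = np.deg2rad([90.0, 210.0, 330.0])
        verts = 0.5 * np.column_stack([np.cos(angles), np.sin(angles)])
        return _polygon_perimeter(verts, n)
    raise ValueError(f"unknown motion label {label!r}; expected one of {LABELS}")


def _polygon_perimeter(vertices: np.ndarray, n: int) -> np.ndarray:
    """Sample n points uniformly by arc length around a closed polygon.

    The start vertex is always included; with n a multiple of the number of
    equal-length side groups the remaining vertices are hit exactly.
    """
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = cum[-1] * np.arange(n) / n
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def _normalize(points: np.ndarray) -> np.ndarray:
    """Centre at the point centroid and scale the larger bbox side to 1."""
    out = points - points.mean(axis=0)
    extent = out.max(axis=0) - out.min(axis=0)
    scale = float(extent.max())
    if scale <= 0.0:
        raise ValueError("degenerate template with zero extent")
    return out / scale


def bbox_diagonal(points: np.ndarray) -> float:
    """Length of the axis-aligned bounding-box diagonal of a point set."""
    extent = np.asarray(points).max(axis=0) - np.asarray(points).min(axis=0)
    return float(np.hypot(*extent))


def generate_template(
    shape_label: str,
    n_raw_points: int = 64,
    rng_seed: int | np.random.Generator | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """Generate a template polyline for one shape class.

    Parameters
    ----------
    shape_label
        One of :data:`LABELS`.
    n_raw_points
        Number of points on the returned polyline (>= 32).
    rng_seed
        Seed or generator for the per-trial jitter.
    jitter
        Std. dev. of the Gaussian point perturbation, as a fraction of the
        template bounding-box diagonal (0 disables jitter).

    Returns
    -------
    ndarray of shape (n_raw_points, 2), centred at the centroid with the
    larger bounding-box side scaled to 1 (before jitter).
    """
    if n_raw_points < N_POINTS:
        raise ValueError(f"n_raw_points must be >= {N_POINTS}, got {n_raw_points}")
    pts = _normalize(_raw_template(shape_label, n_raw_points))
    if jitter > 0.0:
        rng = np.random.default_rng(rng_seed)
        pts = pts + rng.normal(0.0, jitter * bbox_diagonal(pts), size=pts.shape)
    return pts


def resample_trajectory(polyline: np.ndarray, m: int = N_POINTS) -> np.ndarray:
    """Resample a polyline to m points uniformly spaced by cumulative arc length.

    The first and last input points are preserved exactly.  Raises on paths of
    zero total length.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline contains non-finite coordinates")
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise ValueError("polyline has zero total path length")
    s = np.linspace(0.0, total, m)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def emulate_protocol(
    spec: ProtocolSpec | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> list[MotionMatrix]:
    """Emulate one full collection protocol.

    Each participant receives a fixed personal "style" (a slight anisotropic
    stretch and rotation, drawn once per participant) so their repetitions are
    mutually consistent; each trial additionally gets independent point jitter.

    Returns ``spec.total_motions`` motion matrices tagged with participant,
    session and repetition indices.
    """
    spec = spec or ProtocolSpec()
    rng = np.random.default_rng(rng_seed)
    labels = LABELS[: spec.n_labels]
    motions: list[MotionMatrix] = []
    for participant in range(spec.n_participants):
        # personal style, constant across this participant's trials
        sx, sy = rng.normal(1.0, spec.participant_jitter, size=2)
        rot = np.deg2rad(rng.normal(0.0, 5.0))
        cos_r, sin_r = np.cos(rot), np.sin(rot)
        style = np.array([[cos_r, -sin_r], [sin_r, cos_r]]) @ np.diag([abs(sx), abs(sy)])
        for session in range(spec.n_sessions):
            for repetition in range(spec.reps_per_session):
                for label in labels:
                    raw = generate_template(
                        label, spec.n_raw_points, rng, jitter=spec.trial_jitter
                    )
                    styled = (raw - raw.mean(axis=0)) @ style.T + raw.mean(axis=0)
                    motions.append(
                        MotionMatrix(
                            resample_trajectory(styled, N_POINTS),
                            label,
                            meta={
                                "participant": participant,
                                "session": session,
                                "repetition": repetition,
                            },
                        )
                    )
    return motions


def group_by_label(motions: Sequence[MotionMatrix]) -> dict[str, list[MotionMatrix]]:
    """Bucket motions by their class label, preserving order."""
    out: dict[str, list[MotionMatrix]] = {lab: [] for lab in LABELS}
    for m in motions:
        out[m.label].append(m)
    return {lab: ms for lab, ms in out.items() if ms}
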