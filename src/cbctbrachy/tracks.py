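"""Applicator tracks (ordered 3D polylines, tip first) and rigid transforms.

An applicator track is the digitized 3D course of an intrauterine probe, ovoid,
or interstitial needle: an ordered polyline in mm with the physical tip as the
first point. Arc length is measured from the tip along the polyline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

APPLICATOR_TYPES = ("probe", "ovoid", "plastic_needle", "metal_needle")


@dataclass
class ApplicatorTrack:
    """Ordered polyline of reconstruction points in mm, tip first."""

    points: np.ndarray
    kind: str = "plastic_needle"
    name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if len(self.points) < 2:
            raise ValueError("a track needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive track points must be distinct")
        if self.kind not in APPLICATOR_TYPES:
            raise ValueError(f"unknown applicator type {self.kind!r}")

    @property
    def tip(self) -> np.ndarray:
        return self.points[0]

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length from the tip at every point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    @property
    def tip_tangent(self) -> np.ndarray:
        """Unit insertion direction at the tip (from second point toward tip)."""
        d = self.points[0] - self.points[1]
        return d / np.linalg.norm(d)

    def point_at_arc_length(self, s) -> np.ndarray:
        """Position(s) at arc length ``s`` from the tip by linear interpolation."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any(s < -1e-9) or np.any(s > self.length + 1e-9):
            raise ValueError(f"arc length out of range [0, {self.length:.3f}] mm")
        al = self.arc_lengths
        out = np.column_stack([np.interp(s, al, self.points[:, k]) for k in range(3)])
        return out if out.shape[0] > 1 else out[0]

    def resampled(self, step: float = 0.5) -> "ApplicatorTrack":
        """Resample to equidistant points every ``step`` mm of arc length.

        The tip is preserved exactly. A track shorter than one step degrades to
        the two endpoints and emits a warning.
        """
        if step <= 0:
            raise ValueError("step must be positive")
        if self.length < step:
            warnings.warn(
                f"track {self.name!r} shorter ({self.length:.3f} mm) than the "
                f"{step} mm resampling step; returning tip and endpoint only",
                stacklevel=2,
            )
            return ApplicatorTrack(
                np.vstack([self.points[0], self.points[-1]]), self.kind, self.name
            )
        n = int(np.floor(self.length / step + 1e-9)) + 1
        s = np.arange(n) * step
        pts = np.atleast_2d(self.point_at_arc_length(s))
        return ApplicatorTrack(pts, self.kind, self.name)

    def transformed(self, transform: "RigidTransform") -> "ApplicatorTrack":
        return ApplicatorTrack(transform.apply(self.points), self.kind, self.name)


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t mapping between scan frames."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal to 1e-9")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)
        return cls(rot, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_rad(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


# --- JSON implant schema --------------------------------------------------


def tracks_to_dict(tracks: list[ApplicatorTrack], transform: RigidTransform | None = None) -> dict:
    out: dict = {
        "tracks": [
            {"type": t.kind, "name": t.name, "points_mm": t.points.tolist()}
            for t in tracks
        ]
    }
    if transform is not None:
        out["transform"] = {
            "R": transform.rotation.tolist(),
            "t": transform.translation.tolist(),
        }
    return out


def tracks_from_dict(payload: dict) -> tuple[list[ApplicatorTrack], RigidTransform | None]:
    tracks = [
        ApplicatorTrack(np.asarray(t["points_mm"]), t["type"], t.get("name", ""))
        for t in payload["tracks"]
    ]
    transform = None
    if "transform" in payload:
        transform = RigidTransform(
            np.asarray(payload["transform"]["R"]), np.asarray(payload["transform"]["t"])
        )
    return tracks, transform


def save_tracks(path, tracks: list[ApplicatorTrack], transform: RigidTransform | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(tracks_to_dict(tracks, transform), fh, indent=1)


def load_tracks(path) -> tuple[list[ApplicatorTrack], RigidTransform | None]:
    with open(path) as fh:
        return tracks_from_dict(json.load(fh))
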