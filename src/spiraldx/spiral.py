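"""Reference Archimedean spiral and the signed distance-to-spiral transform.

The drawing template is an Archimedean spiral r(θ) = b·θ with b chosen so that
after ``n_loops`` full turns the radius is exactly ``max_radius`` (defaults:
3.75 cm, 4 loops).  A drawn trajectory is reduced to a *signed radial
deviation* series: at each sample the drawn radius minus the template radius
evaluated at the sample's unwrapped polar angle.  Negative values mean the pen
was inside the template spiral.  This is a radial deviation, not a
nearest-point Euclidean distance — the sign convention requires the radial
definition (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .io import DrawingRecording

#: samples closer to the spiral centre than this (cm) have an unreliable
#: polar angle; 0.5 mm
CENTER_EPS_CM = 0.05


@dataclass(frozen=True)
class SpiralTemplate:
    """Archimedean spiral template, r(θ) = pitch_b · θ."""

    max_radius: float = 3.75
    n_loops: int = 4
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.max_radius <= 0:
            raise DomainError(f"max_radius must be positive, got {self.max_radius}")
        if self.n_loops < 1:
            raise DomainError(f"n_loops must be >= 1, got {self.n_loops}")

    @property
    def theta_max(self) -> float:
        return 2.0 * np.pi * self.n_loops

    @property
    def pitch_b(self) -> float:
        """Radius growth per radian (cm/rad)."""
        return self.max_radius / self.theta_max

    def radius(self, theta):
        """Template radius at unwrapped angle(s) theta."""
        return self.pitch_b * np.asarray(theta, dtype=float)

    def point(self, theta):
        """Cartesian template point(s) at unwrapped angle(s) theta."""
        theta = np.asarray(theta, dtype=float)
        r = self.radius(theta)
        return self.center[0] + r * np.cos(theta), self.center[1] + r * np.sin(theta)


def make_reference_spiral(max_radius: float = 3.75, n_loops: int = 4,
                          center=(0.0, 0.0)) -> SpiralTemplate:
    return SpiralTemplate(max_radius=float(max_radius), n_loops=int(n_loops),
                          center=(float(center[0]), float(center[1])))


@dataclass(frozen=True, eq=False)
class DistanceSeries:
    """Signed radial deviation (cm) from the template spiral over time."""

    t: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if self.t.shape != self.d.shape:
            raise ValidationError("t and d must have the same shape")

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DistanceSeries):
            return NotImplemented
        return np.array_equal(self.t, other.t) and np.array_equal(self.d, other.d)


def _unwrap_angles(x: np.ndarray, y: np.ndarray, center) -> np.ndarray:
    """Continuous (unwrapped) polar angle about the template centre.

    Off-centre samples are unwrapped sequentially (branch nearest the previous
    off-centre sample).  Samples within CENTER_EPS_CM of the centre keep their
    measured angle but snapped to the 2π-branch nearest the carried reference
    angle, and do not advance the reference: the angle there is numerically
    fragile and must not seed spurious extra turns.  Before the first reliable
    sample the reference is 0.
    """
    dx = np.asarray(x, dtype=float) - center[0]
    dy = np.asarray(y, dtype=float) - center[1]
    r = np.hypot(dx, dy)
    raw = np.arctan2(dy, dx)
    valid = r >= CENTER_EPS_CM
    if not valid.any():
        raise ValidationError("all samples lie at the spiral centre")
    theta = np.empty_like(raw)
    valid_idx = np.flatnonzero(valid)
    theta[valid_idx] = np.unwrap(raw[valid_idx])
    if valid.all():
        return theta
    # reference for each near-centre sample: last reliable unwrapped angle
    last_valid = np.where(valid, np.arange(len(r)), -1)
    np.maximum.accumulate(last_valid, out=last_valid)
    invalid_idx = np.flatnonzero(~valid)
    ref = np.where(last_valid[invalid_idx] >= 0,
                   theta[np.maximum(last_valid[invalid_idx], 0)], 0.0)
    delta = raw[invalid_idx] - ref
    delta = (delta + np.pi) % (2.0 * np.pi) - np.pi  # wrap to (-pi, pi]
    theta[invalid_idx] = ref + delta
    return theta


def unwrap_angle(rec: DrawingRecording, template: SpiralTemplate) -> np.ndarray:
    """Unwrapped polar angle (radians) of each sample about the template centre."""
    return _unwrap_angles(rec.x, rec.y, template.center)


def signed_distance_series(rec: DrawingRecording, template: SpiralTemplate) -> DistanceSeries:
    """Signed radial deviation of the drawn trajectory from the template.

    d_i = r_i − b·θ_i with r_i the sample's distance to the centre and θ_i its
    unwrapped angle.  An exact template trace maps to the all-zero series;
    d < 0 means the pen ran inside the template.
    """
    if len(rec) < 2:
        raise ValidationError("degenerate recording: need >= 2 samples")
    r = np.hypot(rec.x - template.center[0], rec.y - template.center[1])
    theta = unwrap_angle(rec, template)
    return DistanceSeries(t=rec.t.copy(), d=r - template.radius(theta))


def ensure_outward(rec: DrawingRecording, edge_fraction: float = 0.10) -> DrawingRecording:
    """Return the recording oriented from the centre outwards.

    The overall radial trend is judged by comparing the mean radius over the
    first vs. last ``edge_fraction`` of samples (robust to start/end jitter).
    An inward recording is returned with reversed sample order and timestamps
    t'_i = t_last − t_{n−1−i}, which preserves all inter-sample durations.
    Total and idempotent.
    """
    n = len(rec)
    k = max(1, int(np.floor(edge_fraction * n)))
    r = np.hypot(rec.x, rec.y)
    if np.mean(r[:k]) <= np.mean(r[-k:]):
        return rec
    t_rev = rec.t[-1] - rec.t[::-1]
    return rec.replace_samples(
        t=t_rev, x=rec.x[::-1].copy(), y=rec.y[::-1].copy(), force=rec.force[::-1].copy()
    )
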