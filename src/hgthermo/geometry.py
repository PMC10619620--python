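"""Host symmetry axis, guest tilt-angle series and portal-flip detection.

The host axis runs portal to portal (centroid-to-centroid of the two
portal atom rings, or the symmetry axis from the coordinate covariance
of ring atoms).  The guest axis is an atom-pair vector (hydroxyl O to
cage centroid for mono-ols, O-to-O for diols) or a principal axis.
The tilt angle is the angle between the two; by default it is
orientation-folded into [0, 90] deg (the sign of either axis is
arbitrary), while the unfolded angle in [0, 180] distinguishes the two
portal orientations and feeds the flip detector.

Flips are detected with a two-threshold hysteresis to suppress
chatter: the guest must cross well past the midpoint before a state
change is registered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AxisSpec",
    "TiltSeries",
    "FlipEvent",
    "host_axis",
    "guest_axis",
    "tilt_series",
    "flip_events",
]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n <= 1e-6:
        raise ValueError("degenerate axis (norm <= 1e-6)")
    return v / n


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Symmetry axis of a ring-like selection: the direction of least
    coordinate variance (normal to the ring plane)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("principal axis needs >= 3 atoms")
    cov = np.cov((pts - pts.mean(axis=0)).T)
    w, v = np.linalg.eigh(cov)
    return _unit(v[:, 0])


@dataclass(frozen=True)
class AxisSpec:
    """Atom selections defining the host and guest axes.

    ``portal1``/``portal2`` select the two portal rings (host axis =
    centroid(portal1) -> centroid(portal2)); with ``host_mode=
    "principal"`` the host axis is the symmetry axis of
    portal1+portal2 ring atoms instead.  The guest axis is the vector
    ``guest_tail -> guest_head`` (indices of single atoms or
    selections whose centroids are used).
    """

    portal1: tuple[int, ...]
    portal2: tuple[int, ...]
    guest_tail: tuple[int, ...]
    guest_head: tuple[int, ...]
    host_mode: str = "portal-centroids"

    def __post_init__(self) -> None:
        for sel in (self.portal1, self.portal2, self.guest_tail, self.guest_head):
            if len(sel) == 0:
                raise ValueError("empty atom selection")
        if self.host_mode not in ("portal-centroids", "principal"):
            raise ValueError(f"unknown host_mode {self.host_mode!r}")


def host_axis(coords: np.ndarray, spec: AxisSpec) -> np.ndarray:
    """Unit host axis for one frame of coordinates (N, 3)."""
    coords = np.asarray(coords, dtype=float)
    if spec.host_mode == "principal":
        ring = coords[list(spec.portal1) + list(spec.portal2)]
        return _principal_axis(ring)
    c1 = coords[list(spec.portal1)].mean(axis=0)
    c2 = coords[list(spec.portal2)].mean(axis=0)
    return _unit(c2 - c1)


def guest_axis(coords: np.ndarray, spec: AxisSpec) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    tail = coords[list(spec.guest_tail)].mean(axis=0)
    head = coords[list(spec.guest_head)].mean(axis=0)
    return _unit(head - tail)


@dataclass(frozen=True)
class TiltSeries:
    """Per-frame guest tilt angle, degrees."""

    angles: np.ndarray            # deg, in [0, 180]
    times: np.ndarray
    folded: bool = True
    excluded_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.size and (a.min() < 0 or a.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")
        if self.folded and a.size and a.max() > 90 + 1e-12:
            raise ValueError("folded angles must lie in [0, 90] degrees")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    @property
    def mean(self) -> float:
        return float(self.angles.mean())

    @property
    def fluctuation(self) -> float:
        """Standard deviation of the tilt angle, degrees."""
        return float(self.angles.std(ddof=1)) if self.angles.size > 1 else 0.0


def tilt_series(
    frames: Sequence[np.ndarray],
    spec: AxisSpec,
    times: Sequence[float] | None = None,
    folded: bool = True,
) -> TiltSeries:
    """Guest tilt angle relative to the host axis for each frame.

    Folded: theta = arccos(|u_host . u_guest|) in [0, 90].  Unfolded
    (for flip detection): theta = arccos(u_host . u_guest) in [0, 180].
    Frames with a degenerate axis are excluded and reported.
    """
    angles, kept, excluded = [], [], []
    for i, coords in enumerate(frames):
        try:
            uh = host_axis(coords, spec)
            ug = guest_axis(coords, spec)
        except ValueError:
            excluded.append(i)
            continue
        c = float(np.clip(np.dot(uh, ug), -1.0, 1.0))
        angles.append(np.degrees(np.arccos(abs(c) if folded else c)))
        kept.append(i)
    t = np.asarray(times, float)[kept] if times is not None else np.asarray(kept, float)
    return TiltSeries(
        angles=np.asarray(angles), times=t, folded=folded,
        excluded_frames=tuple(excluded),
    )


@dataclass(frozen=True)
class FlipEvent:
    frame: int          # index into the series where the new state begins
    time: float
    from_state: str     # "A" (aligned) or "B" (anti-aligned)
    to_state: str


def flip_events(
    series: TiltSeries,
    enter_a: float = 60.0,
    enter_b: float = 120.0,
) -> tuple[list[FlipEvent], list[float]]:
    """Hysteresis two-state flip detection on an unfolded tilt series.

    State A (aligned with the reference portal) is entered when the
    angle drops below ``enter_a``; state B when it rises above
    ``enter_b``.  Angles in the dead band between the thresholds never
    change the state, so noise inside the band produces no events.
    Returns the flip events and the dwell times between consecutive
    flips (in the series' time unit).
    """
    if series.folded:
        raise ValueError("flip detection requires an unfolded (0-180 deg) series")
    if not (0.0 < enter_a < enter_b < 180.0):
        raise ValueError("thresholds must satisfy 0 < enter_a < enter_b < 180")
    th = series.angles
    t = series.times
    state: str | None = None
    last_flip_time: float | None = None
    events: list[FlipEvent] = []
    dwells: list[float] = []
    for i, a in enumerate(th):
        new = "A" if a < enter_a else ("B" if a > enter_b else None)
        if new is None:
            continue
        if state is None:
            state = new
            continue
        if new != state:
            events.append(FlipEvent(frame=i, time=float(t[i]), from_state=state, to_state=new))
            if last_flip_time is not None:
                dwells.append(float(t[i]) - last_flip_time)
            last_flip_time = float(t[i])
            state = new
    return events, dwells
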