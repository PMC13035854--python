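"""Time- and space-resolved illumination protocols driving photolysis.

Intensity is in arbitrary units: only the product k_ph * A is physical,
since the photon flux is never calibrated.  The convention used by the
calibrated defaults is A = 1 for full illumination.

Kinds
-----
disk_step       continuous disk of radius rho with soft edge w_s
pulse_train     the disk gated by a cycle clock (t_on light, t_off dark)
sigmoid_control A / (1 + exp((r - rho)/w_s)); the action space of the
                control layer (radius and amplitude vary per control step)
mask2d          a time-indexed binary image for the 2D chemistry-only mode
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["LightProtocol", "light_intensity", "protocol_from_config",
           "mask_at", "disk_mask", "moving_circle_mask"]

_KINDS = ("disk_step", "pulse_train", "sigmoid_control", "mask2d")


@dataclass
class LightProtocol:
    """A light protocol; see module docstring for the kinds."""

    kind: str
    A: float = 1.0                   # intensity amplitude (arb. units)
    rho: float = 37.5                # disk / sigmoid radius (um)
    w_s: float = 1.0                 # edge softness (um); 0 = hard edge
    t_on: float = np.inf             # on-duration per cycle (s)
    t_off: float = 0.0               # off-duration per cycle (s)
    n_cyc: int = 1                   # number of cycles (pulse_train)
    # mask2d only: stack of binary frames, the pixel size, and the frame period
    mask: Optional[np.ndarray] = field(default=None, repr=False)
    pixel_size: float = 1.0          # um / pixel
    frame_dt: float = np.inf         # s per mask frame (inf = static mask)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if self.A < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.A}")
        for name in ("rho", "w_s", "t_on", "t_off", "frame_dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_cyc < 1:
            raise ValueError(f"n_cyc must be >= 1, got {self.n_cyc}")
        if self.kind == "mask2d":
            if self.mask is None:
                raise ValueError("mask2d protocol requires a mask")
            m = np.asarray(self.mask)
            if m.ndim == 2:
                m = m[None]
            self.mask = (m > 0.5).astype(float)

    # -- time gating --------------------------------------------------------
    def gate(self, t: float) -> float:
        """1.0 inside an on-window at time t, else 0.0."""
        if t < 0:
            return 0.0
        if self.kind == "pulse_train":
            period = self.t_on + self.t_off
            if t >= self.n_cyc * period:
                return 0.0
            return 1.0 if (t % period) < self.t_on else 0.0
        if np.isfinite(self.t_on):
            return 1.0 if t < self.t_on else 0.0
        return 1.0

    def gate_array(self, times) -> np.ndarray:
        """Vectorized :meth:`gate` over an array of times."""
        t = np.asarray(times, dtype=float)
        if self.kind == "pulse_train":
            period = self.t_on + self.t_off
            on = ((t % period) < self.t_on) & (t < self.n_cyc * period)
            return np.where((t >= 0) & on, 1.0, 0.0)
        if np.isfinite(self.t_on):
            return np.where((t >= 0) & (t < self.t_on), 1.0, 0.0)
        return np.where(t >= 0, 1.0, 0.0)

    def radial_profile(self, r) -> np.ndarray:
        """Spatial factor of the intensity on radii r (no time gating)."""
        r = np.asarray(r, dtype=float)
        if self.kind == "mask2d":
            raise ValueError("mask2d protocols have no radial profile; "
                             "use mask_at on a 2D grid")
        if self.w_s == 0.0:
            return np.where(r <= self.rho, self.A, 0.0)
        # logistic edge; numerically safe for large exponents
        x = np.clip((r - self.rho) / self.w_s, -60.0, 60.0)
        return self.A / (1.0 + np.exp(x))


def light_intensity(protocol: LightProtocol, r, t: float) -> np.ndarray:
    """Intensity at radius/radii ``r`` and time ``t`` (>= 0)."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return protocol.radial_profile(r) * protocol.gate(t)


def mask_at(protocol: LightProtocol, t: float) -> np.ndarray:
    """The active 2D intensity image (A * binary mask) at time t."""
    if protocol.kind != "mask2d":
        raise ValueError("mask_at is only defined for mask2d protocols")
    if protocol.gate(t) == 0.0:
        return np.zeros_like(protocol.mask[0])
    if np.isfinite(protocol.frame_dt):
        idx = int(t / protocol.frame_dt) % protocol.mask.shape[0]
    else:
        idx = 0
    return protocol.A * protocol.mask[idx]


def protocol_from_config(record: dict) -> LightProtocol:
    """Build a validated protocol from a config mapping.

    Accepts ``diameter`` (um) as an alternative to ``radius``; 2D masks may
    be given inline as arrays or as a path to a grayscale image
    (thresholded at 0.5).
    """
    rec = dict(record)
    kind = rec.pop("kind", None)
    if kind not in _KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}")
    kwargs: dict = {"kind": kind}
    if "diameter" in rec and "radius" in rec:
        raise ValueError("give either 'diameter' or 'radius', not both")
    if "diameter" in rec:
        kwargs["rho"] = float(rec.pop("diameter")) / 2.0
    if "radius" in rec:
        kwargs["rho"] = float(rec.pop("radius"))
    renames = {"amplitude": "A", "edge_width": "w_s"}
    for src, dst in renames.items():
        if src in rec:
            kwargs[dst] = rec.pop(src)
    for key in ("A", "w_s", "t_on", "t_off", "n_cyc", "pixel_size", "frame_dt"):
        if key in rec:
            kwargs[key] = rec.pop(key)
    if "mask" in rec:
        mask = rec.pop("mask")
        if isinstance(mask, str):
            import imageio.v3 as iio

            img = np.asarray(iio.imread(mask), dtype=float)
            if img.ndim == 3:
                img = img.mean(axis=-1)
            mask = img / img.max() if img.max() > 0 else img
        kwargs["mask"] = np.asarray(mask)
    if rec:
        raise ValueError(f"unknown protocol keys: {sorted(rec)}")
    if "n_cyc" in kwargs:
        kwargs["n_cyc"] = int(kwargs["n_cyc"])
    return LightProtocol(**kwargs)


# -- mask helpers for the 2D chemistry mode ---------------------------------

def disk_mask(n: int, pixel_size: float, radius: float,
              center=None) -> np.ndarray:
    """Binary disk mask on an n x n pixel grid (pixel centers)."""
    xy = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    X, Y = np.meshgrid(xy, xy)
    cx, cy = (0.0, 0.0) if center is None else center
    return ((X - cx) ** 2 + (Y - cy) ** 2 <= radius ** 2).astype(float)


def moving_circle_mask(n: int, pixel_size: float, radius: float,
                       orbit_radius: float, freq_hz: float, frame_dt: float,
                       n_frames: int) -> np.ndarray:
    """Frames of a circular spot orbiting at freq_hz (dynamic-pattern demo)."""
    frames = []
    for k in range(n_frames):
        t = k * frame_dt
        ang = 2.0 * np.pi * freq_hz * t
        frames.append(disk_mask(n, pixel_size, radius,
                                center=(orbit_radius * np.cos(ang),
                                        orbit_radius * np.sin(ang))))
    return np.stack(frames)
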