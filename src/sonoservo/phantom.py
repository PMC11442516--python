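"""Synthetic leg-vessel ultrasound phantom.

Generates B-mode cross-section frames and X-Plane color-Doppler frames of a
superficial leg artery with exactly known ground truth, plus a spring–damper
skin-contact model, so the trackers and the closed servo loop can be exercised
and measured without any real ultrasound data.

World model
-----------
The phantom lives in the robot base frame {b}, in millimetres.  The skin is a
height surface (flat ``z = 0`` by default); the vessel runs roughly along the
base x-axis at a constant depth below the skin, with a sinusoidal lateral
(y) deviation, and optionally a linear radius taper along its length.

Imaging model
-------------
The probe frame {p} has its z-axis pointing into the tissue and its x-axis
along the vessel (elevational direction).  The rendered cross-section is the
plane spanned by the probe y-axis (image columns) and z-axis (image rows):
pixel ``(x, y)`` means column x, row y, origin top-left, 0-based.  With the
default display convention the image x-axis and the probe y-axis point in
*opposite* display directions (``lateral_flip=False`` puts a structure lying
along +probe-y on the right half of the image); ``lateral_flip=True`` mirrors
the columns, modelling the opposite ultrasound-station convention.  B-mode
appearance is a smooth depth-attenuated tissue background with tissue-anchored
texture, multiplicative speckle, a bright skin line and a hypoechoic (dark)
lumen ellipse with a thin echogenic wall.  No wave propagation or Doppler
physics is simulated.

The Doppler cross-section paints red flow pixels (inside the standard
red-flow HSV ranges: hue in [0,10] or [170,180], saturation >= 50,
value >= 20, on H in [0,180] / S,V in [0,255] scales) over the lumen; the
flow radius pulses with a cardiac period, and with a seeded probability a
frame's flow patch is split into disjoint fragments, reproducing the
unconnected colored areas that pulsatile flow produces on real stations.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

from .transforms import HomogeneousTransform

__all__ = [
    "PhantomConfig",
    "VesselGeometry",
    "BModeFrame",
    "DopplerXPlaneFrame",
    "ContactSurface",
    "generate_geometry",
    "render_bmode",
    "render_doppler",
    "contact_wrench",
    "canonical_probe_pose",
    "save_frames",
    "load_frames",
    "write_ground_truth_csv",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class PhantomConfig:
    """Parameters of the synthetic vessel phantom.

    Defaults mirror the acquisition geometry of a clinical leg scan: 512 px
    square images at 0.098 mm/px (50 mm depth), a ~5 mm-radius artery about
    20 mm under the skin, and a gently curving centerline.
    """

    image_width_px: int = 512
    image_height_px: int = 512
    spacing_mm_per_px: float = 0.098
    depth_mm: float = 50.0
    vessel_radius_mm: float = 5.0
    centerline_amplitude_mm: float = 5.0
    centerline_wavelength_mm: float = 100.0
    vessel_depth_mm: float = 20.0
    speckle_noise_level: float = 0.3
    pulsatility_period_s: float = 1.0
    fragment_probability: float = 0.3
    rng_seed: int = 0
    # linear radius reduction over the vessel length (0.3 -> 30 % taper)
    radius_taper_fraction: float = 0.0
    length_mm: float = 250.0
    # where the vessel entry point sits in the base frame (mm)
    origin_mm: tuple = (300.0, 0.0)
    # ultrasound-station display convention for the image x-axis
    lateral_flip: bool = False
    bmode_rate_hz: float = 25.0
    doppler_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.spacing_mm_per_px <= 0:
            raise ValueError("spacing must be positive")
        if self.depth_mm <= 0 or self.vessel_radius_mm <= 0:
            raise ValueError("depth and vessel radius must be positive")
        if self.centerline_wavelength_mm <= 0:
            raise ValueError("centerline wavelength must be positive")
        if self.length_mm <= 0:
            raise ValueError("vessel length must be positive")
        if self.vessel_depth_mm <= 0:
            raise ValueError("vessel depth must be positive")
        if not 0.0 <= self.speckle_noise_level <= 1.0:
            raise ValueError("speckle_noise_level must lie in [0,1]")
        if not 0.0 <= self.fragment_probability <= 1.0:
            raise ValueError("fragment_probability must lie in [0,1]")
        if not 0.0 <= self.radius_taper_fraction < 1.0:
            raise ValueError("radius_taper_fraction must lie in [0,1)")
        if self.pulsatility_period_s <= 0:
            raise ValueError("pulsatility_period_s must be positive")
        if self.vessel_depth_mm + self.vessel_radius_mm >= self.depth_mm:
            raise ValueError("vessel must fit above the imaging depth")
        fov_mm = self.image_width_px * self.spacing_mm_per_px
        if fov_mm < 2.0 * self.vessel_radius_mm:
            raise ValueError("field of view too narrow for the vessel")

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "origin_mm" in data:
            data["origin_mm"] = tuple(data["origin_mm"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["origin_mm"] = list(self.origin_mm)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class VesselGeometry:
    """Parametric vessel centerline and radius profile in the base frame (mm).

    ``centerline(u)`` maps the axial coordinate u in [0, length_mm] to a 3D
    point; ``radius_profile(u)`` gives the local lumen radius.  ``arc_length``
    converts axial coordinate to true arc length along the curve.
    """

    centerline: Callable[[np.ndarray], np.ndarray]
    radius_profile: Callable[[np.ndarray], np.ndarray]
    length_mm: float

    def arc_length(self, u: float, n: int = 512) -> float:
        """Arc length of the centerline from 0 to u (numeric quadrature)."""
        s = np.linspace(0.0, u, n)
        pts = self.centerline(s)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class BModeFrame:
    pixels: np.ndarray  # uint8, (H, W)
    spacing_mm_per_px: float
    timestamp_s: float = 0.0
    true_center_px: Optional[tuple] = None


@dataclass
class DopplerXPlaneFrame:
    cross_section: np.ndarray  # uint8 RGB, (H, W, 3)
    longitudinal: np.ndarray  # uint8 RGB, (H, W, 3)
    spacing_mm_per_px: float
    timestamp_s: float = 0.0
    true_center_px: Optional[tuple] = None


@dataclass
class ContactSurface:
    """Skin model: a height surface with a normal spring–damper response.

    ``height_mm`` is either a constant or a callable (x_mm, y_mm) -> z_mm.
    Stiffness is in N/mm and damping in N·s/mm; a soft-tissue stiffness of
    about 1 N/mm gives a ~5 mm indentation at the 5 N scan force.
    """

    height_mm: object = 0.0
    stiffness_N_per_mm: float = 1.0
    damping_Ns_per_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.stiffness_N_per_mm <= 0:
            raise ValueError("stiffness must be positive")
        if self.damping_Ns_per_mm < 0:
            raise ValueError("damping must be nonnegative")

    def height_at(self, x_mm: float, y_mm: float) -> float:
        if callable(self.height_mm):
            return float(self.height_mm(x_mm, y_mm))
        return float(self.height_mm)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------
def generate_geometry(config: PhantomConfig) -> VesselGeometry:
    """Build the vessel centerline/radius model from the phantom config.

    The centerline is a sinusoidal lateral deviation about a straight axis:
    ``(ox + u, oy + A sin(2 pi u / lambda), -vessel_depth)`` for axial
    coordinate u, with an optional linear radius taper.  Deterministic given
    the config (the stochastic parts of the phantom live in the renderers).
    """
    ox, oy = config.origin_mm
    amp = float(config.centerline_amplitude_mm)
    wav = float(config.centerline_wavelength_mm)
    depth = float(config.vessel_depth_mm)
    r0 = float(config.vessel_radius_mm)
    taper = float(config.radius_taper_fraction)
    length = float(config.length_mm)

    def centerline(u):
        u = np.asarray(u, dtype=float)
        pts = np.stack(
            [
                ox + u,
                oy + amp * np.sin(2.0 * np.pi * u / wav),
                np.full_like(u, -depth),
            ],
            axis=-1,
        )
        return pts

    def radius_profile(u):
        u = np.asarray(u, dtype=float)
        frac = np.clip(u / length, 0.0, 1.0)
        return r0 * (1.0 - taper * frac)

    return VesselGeometry(centerline=centerline, radius_profile=radius_profile, length_mm=length)


def canonical_probe_pose(config: PhantomConfig, u_mm: float, lateral_mm: float = 0.0,
                         height_mm: float = 0.0) -> HomogeneousTransform:
    """Probe pose over axial station ``u_mm``, offset ``lateral_mm`` in base y.

    The canonical scanning orientation keeps probe x along base x and probe z
    pointing down into the tissue (a 180 degree rotation about the base
    x-axis), matching the constant-orientation scan protocol.
    """
    ox, oy = config.origin_mm
    rot = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    return HomogeneousTransform.from_rotation_translation(
        rot, [ox + u_mm, oy + lateral_mm, height_mm], from_frame="p", to_frame="b"
    )


def _locate_cross_section(
    geometry: VesselGeometry, probe_pose: HomogeneousTransform, config: PhantomConfig
):
    """Intersect the centerline with the imaging plane.

    Returns ``(u_star, lateral_mm, depth_mm, radius_mm)`` where lateral/depth
    are the in-plane coordinates of the vessel center relative to the probe
    origin (along probe y and probe z), or None when the centerline never
    crosses the plane near the probe.
    """
    p = probe_pose.translation
    r = probe_pose.rotation
    normal = r[:, 0]  # probe x-axis = elevational direction (plane normal)
    u = np.linspace(0.0, geometry.length_mm, 2048)
    d = (geometry.centerline(u) - p) @ normal
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if len(sign_change) == 0:
        # no crossing: accept only an endpoint within half a vessel radius
        if np.min(np.abs(d)) > 0.5 * float(geometry.radius_profile(0.0)):
            return None
        i = int(np.argmin(np.abs(d)))
        u_star = u[i]
    else:
        # pick the crossing closest to the probe
        best, best_dist = None, np.inf
        for i in sign_change:
            u0, u1 = u[i], u[i + 1]
            d0, d1 = d[i], d[i + 1]
            u_c = u0 if d1 == d0 else u0 - d0 * (u1 - u0) / (d1 - d0)
            dist = np.linalg.norm(geometry.centerline(u_c) - p)
            if dist < best_dist:
                best, best_dist = u_c, dist
        u_star = best
    c = geometry.centerline(np.array([u_star]))[0]
    rel = c - p
    lateral = float(rel @ r[:, 1])
    depth = float(rel @ r[:, 2])
    return float(u_star), lateral, depth, float(geometry.radius_profile(u_star))


def _center_pixel(lateral_mm: float, depth_mm: float, config: PhantomConfig):
    s = config.spacing_mm_per_px
    sign = -1.0 if config.lateral_flip else 1.0
    x = config.image_width_px / 2.0 + sign * lateral_mm / s
    y = depth_mm / s
    return x, y


def _frame_rng(config: PhantomConfig, timestamp_s: float, salt: str) -> np.random.Generator:
    """Deterministic per-frame RNG: same config/seed/time -> identical frame."""
    key = f"{salt}:{int(round(timestamp_s * 1e6))}".encode()
    digest = int.from_bytes(hashlib.sha256(key).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, digest]))


def _texture_components(seed: int):
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 991]))
    comps = []
    for _ in range(6):
        k = rng.uniform(0.05, 0.5, size=3)  # cycles/mm
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        comps.append((k, phase, amp))
    return comps


def _tissue_texture(probe_pose: HomogeneousTransform, lat_mm, dep_mm, seed: int):
    """Smooth tissue-anchored texture: a fixed sum of 3D sinusoids.

    Anchoring the texture to world coordinates (not image coordinates) makes
    structures translate correctly when the probe moves, which matters for
    template matching.  The pixel world coordinate is affine in (row, col),
    so each sinusoid separates into outer products of 1D factors:
    sin(a_col + b_row + c) = sin(a+c) cos(b) + cos(a+c) sin(b).
    """
    p = probe_pose.translation
    r = probe_pose.rotation
    comps = _texture_components(seed)
    # sum of rank-1 outer products Im(e^{ib} x e^{ia}) via one complex matmul
    A = np.empty((len(comps), len(lat_mm)), dtype=complex)
    B = np.empty((len(dep_mm), len(comps)), dtype=complex)
    for i, (k, phase, amp) in enumerate(comps):
        a = 2 * np.pi * (k @ r[:, 1]) * lat_mm + (2 * np.pi * (k @ p) + phase)
        b = 2 * np.pi * (k @ r[:, 2]) * dep_mm
        A[i] = np.exp(1j * a)
        B[:, i] = amp * np.exp(1j * b)
    return (B @ A).imag / 4.0


def _plane_coords(config: PhantomConfig):
    """In-plane pixel coordinates: lat (along probe y) and dep (probe z), mm."""
    s = config.spacing_mm_per_px
    w, h = config.image_width_px, config.image_height_px
    sign = -1.0 if config.lateral_flip else 1.0
    lat = (np.arange(w, dtype=float) - w / 2.0) * s * sign
    dep = np.arange(h, dtype=float) * s
    return lat, dep


def _lumen_mask(xgrid, ygrid, cx, cy, rx_px, ry_px, soft_px=2.0):
    """Soft elliptical disk: 1 inside, 0 outside, smooth border."""
    rho = np.sqrt(((xgrid - cx) / rx_px) ** 2 + ((ygrid - cy) / ry_px) ** 2)
    edge = soft_px / max(rx_px, 1e-6)
    return np.clip((1.0 + edge - rho) / max(edge, 1e-9), 0.0, 1.0)


def render_bmode(
    geometry: VesselGeometry,
    probe_pose: HomogeneousTransform,
    config: PhantomConfig,
    time_s: float = 0.0,
) -> BModeFrame:
    """Render a grayscale B-mode cross-section at the given probe pose.

    The lumen appears as a dark ellipse with a thin bright wall on a
    depth-attenuated, textured, speckled tissue background.  The frame's
    ``true_center_px`` is the analytic projection of the vessel center onto
    the imaging plane, or None when the vessel is outside the field of view.
    """
    w, h = config.image_width_px, config.image_height_px
    s = config.spacing_mm_per_px
    lat, dep = _plane_coords(config)

    # depth-attenuated background with tissue-anchored texture
    bg = (60.0 + 110.0 * np.exp(-dep / 45.0))[:, None]
    tex = _tissue_texture(probe_pose, lat, dep, config.rng_seed)
    img = bg * (1.0 + 0.22 * tex)

    # bright skin line in the first ~1.5 mm
    img += (90.0 * np.exp(-0.5 * ((dep - 0.8) / 0.5) ** 2))[:, None]

    loc = _locate_cross_section(geometry, probe_pose, config)
    center = None
    if loc is not None:
        _, lateral, depth, radius = loc
        cx, cy = _center_pixel(lateral, depth, config)
        if 0 <= cx < w and 0 <= cy < h:
            center = (cx, cy)
        rx = radius / s
        ry = 0.88 * rx  # slightly elliptical lumen
        pad = rx + 6.0
        x0 = int(max(0, np.floor(cx - pad)))
        x1 = int(min(w, np.ceil(cx + pad) + 1))
        y0 = int(max(0, np.floor(cy - pad)))
        y1 = int(min(h, np.ceil(cy + pad) + 1))
        if x1 > x0 and y1 > y0:
            xg, yg = np.meshgrid(np.arange(x0, x1, dtype=float), np.arange(y0, y1, dtype=float))
            lumen = _lumen_mask(xg, yg, cx, cy, rx, ry)
            grow = 1.2 / s * 0.35
            wall = _lumen_mask(xg, yg, cx, cy, rx + grow, ry + grow) - lumen
            img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1.0 - 0.88 * lumen) + 55.0 * np.clip(
                wall, 0, 1
            )

    # multiplicative speckle
    level = config.speckle_noise_level
    if level > 0:
        rng = _frame_rng(config, time_s, "bmode")
        speckle = rng.gamma(shape=4.0, scale=0.25, size=img.shape)
        img = img * ((1.0 - level) + level * speckle)

    pixels = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return BModeFrame(
        pixels=pixels, spacing_mm_per_px=s, timestamp_s=time_s, true_center_px=center
    )


# red flow palette (OpenCV-style HSV: H in [0,180], S,V in [0,255])
_FLOW_HUES = np.array([2.0, 5.0, 8.0, 174.0, 178.0])


def _hsv_to_rgb_u8(h, s, v):
    """HSV (H in [0,180], S,V in [0,255]) -> uint8 RGB, vectorized."""
    from skimage.color import hsv2rgb

    hsv = np.stack([np.asarray(h) / 180.0, np.asarray(s) / 255.0, np.asarray(v) / 255.0], axis=-1)
    return (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)


def render_doppler(
    geometry: VesselGeometry,
    probe_pose: HomogeneousTransform,
    time_s: float,
    config: PhantomConfig,
) -> DopplerXPlaneFrame:
    """Render an X-Plane color-Doppler frame (cross-section + longitudinal).

    Red flow pixels cover the lumen cross-section; the flow radius pulses
    with the cardiac period and, with probability ``fragment_probability``
    per frame (seeded), the patch is cut into >= 2 disjoint fragments whose
    area-weighted centroid stays inside the lumen.  The longitudinal plane is
    rendered for completeness; the trackers consume only the cross-section.
    """
    w, h = config.image_width_px, config.image_height_px
    s = config.spacing_mm_per_px

    base = render_bmode(geometry, probe_pose, config, time_s=time_s)
    # desaturated (gray) background: S = 0, safely outside the red S-range
    cross = np.repeat(base.pixels[:, :, None], 3, axis=2).astype(np.uint8)

    loc = _locate_cross_section(geometry, probe_pose, config)
    center = base.true_center_px
    rng = _frame_rng(config, time_s, "doppler")

    if loc is not None and center is not None:
        _, lateral, depth, radius = loc
        cx, cy = center
        phase = 2.0 * np.pi * time_s / config.pulsatility_period_s
        pulse = 0.78 + 0.18 * np.sin(phase)
        r_px = max(2.0, radius / s * pulse)

        x0 = int(max(0, np.floor(cx - r_px - 3)))
        x1 = int(min(w, np.ceil(cx + r_px + 4)))
        y0 = int(max(0, np.floor(cy - r_px - 3)))
        y1 = int(min(h, np.ceil(cy + r_px + 4)))
        xg, yg = np.meshgrid(np.arange(x0, x1, dtype=float), np.arange(y0, y1, dtype=float))
        rho = np.sqrt((xg - cx) ** 2 + (yg - cy) ** 2)
        flow = rho <= r_px

        if flow.any() and config.fragment_probability > 0 and (
            rng.random() < config.fragment_probability
        ):
            # cut the disk with 1-2 narrow stripes through (near) the center:
            # the lumpy, disconnected flow patches of pulsatile Doppler
            n_cuts = 1 + int(rng.random() < 0.35)
            for _ in range(n_cuts):
                ang = rng.uniform(0.0, np.pi)
                offset = rng.uniform(-0.25, 0.25) * r_px
                width = rng.uniform(2.5, 4.0)  # wide enough to defeat 8-connectivity
                n = np.array([np.cos(ang), np.sin(ang)])
                dist = (xg - cx) * n[0] + (yg - cy) * n[1] - offset
                flow &= np.abs(dist) > width / 2.0

        if flow.any():
            # radial red shading, all inside the red HSV ranges
            rr = np.clip(rho / max(r_px, 1e-9), 0.0, 1.0)
            hue = _FLOW_HUES[(rng.integers(0, len(_FLOW_HUES), size=rho.shape))]
            sat = (255.0 - 80.0 * rr).clip(130, 255)
            val = (235.0 - 120.0 * rr).clip(80, 255)
            rgb = _hsv_to_rgb_u8(hue, sat, val)
            patch = cross[y0:y1, x0:x1]
            patch[flow] = rgb[flow]
            cross[y0:y1, x0:x1] = patch

    # longitudinal plane: red band at the vessel depth (display only)
    longitudinal = np.repeat(base.pixels[:, :, None], 3, axis=2).astype(np.uint8)
    if loc is not None:
        _, _, depth, radius = loc
        y_top = int(np.clip((depth - radius * 0.8) / s, 0, h - 1))
        y_bot = int(np.clip((depth + radius * 0.8) / s, 0, h - 1))
        band = _hsv_to_rgb_u8(
            np.full((max(y_bot - y_top, 1), w), 4.0),
            np.full((max(y_bot - y_top, 1), w), 210.0),
            np.full((max(y_bot - y_top, 1), w), 190.0),
        )
        longitudinal[y_top:y_bot, :] = band

    return DopplerXPlaneFrame(
        cross_section=cross,
        longitudinal=longitudinal,
        spacing_mm_per_px=s,
        timestamp_s=time_s,
        true_center_px=center,
    )


# ---------------------------------------------------------------------------
# contact model
# ---------------------------------------------------------------------------
def contact_wrench(
    probe_pose: HomogeneousTransform,
    probe_velocity_mm_s: np.ndarray,
    surface: Optional[ContactSurface],
    flange_point_mm: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Wrench the probe exerts on the skin, in the base frame.

    Returns ``(fx, fy, fz [N], tx, ty, tz [N·m])``.  Above the surface the
    wrench is zero; below it, a spring–damper normal force proportional to
    the penetration acts along the probe z-axis (which points into the
    tissue), so the force component along probe z is always >= 0.  If
    ``flange_point_mm`` is given the torque of the tip force about that point
    is included, otherwise the torque is zero.
    """
    w = np.zeros(6)
    if surface is None:
        return w
    tip = probe_pose.translation
    z_axis = probe_pose.rotation[:, 2]
    height = surface.height_at(tip[0], tip[1])
    penetration = height - tip[2]  # mm; positive when below the skin
    if penetration <= 0.0:
        return w
    v = np.asarray(probe_velocity_mm_s, dtype=float)
    pen_rate = -float(v[2])  # mm/s; positive while pressing in
    f_normal = surface.stiffness_N_per_mm * penetration + surface.damping_Ns_per_mm * pen_rate
    f_normal = max(f_normal, 0.0)
    force = f_normal * z_axis  # probe-on-skin force points into the tissue
    w[:3] = force
    if flange_point_mm is not None:
        lever_m = (tip - np.asarray(flange_point_mm, dtype=float)) / 1000.0
        w[3:] = np.cross(lever_m, force)
    return w


# ---------------------------------------------------------------------------
# frame I/O
# ---------------------------------------------------------------------------
def save_frames(frames: Sequence, directory, prefix: str = "frame") -> list:
    """Save frames as PNGs (gray for B-mode, RGB for Doppler cross-sections).

    Returns the written paths.  Doppler frames produce ``*_xs.png`` and
    ``*_long.png`` pairs.  For a single multi-page file use
    :func:`save_tiff_stack`.
    """
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        if isinstance(frame, BModeFrame):
            path = directory / f"{prefix}_{i:05d}.png"
            iio.imwrite(path, frame.pixels)
            paths.append(path)
        else:
            p1 = directory / f"{prefix}_{i:05d}_xs.png"
            p2 = directory / f"{prefix}_{i:05d}_long.png"
            iio.imwrite(p1, frame.cross_section)
            iio.imwrite(p2, frame.longitudinal)
            paths.extend([p1, p2])
    return paths


def save_tiff_stack(frames: Sequence, path) -> None:
    """Save a sequence of frames of one kind as a multi-page TIFF stack."""
    import tifffile

    arrays = [
        f.pixels if isinstance(f, BModeFrame) else f.cross_section for f in frames
    ]
    tifffile.imwrite(path, np.stack(arrays))


def load_tiff_stack(path, spacing_mm_per_px: float):
    """Load a TIFF stack back as B-mode (2D pages) or Doppler (RGB) frames."""
    import tifffile

    stack = tifffile.imread(path)
    frames = []
    for i, page in enumerate(stack):
        if page.ndim == 3:
            frames.append(
                DopplerXPlaneFrame(
                    cross_section=page,
                    longitudinal=page,
                    spacing_mm_per_px=spacing_mm_per_px,
                    timestamp_s=float(i),
                )
            )
        else:
            frames.append(
                BModeFrame(pixels=page, spacing_mm_per_px=spacing_mm_per_px, timestamp_s=float(i))
            )
    return frames


def load_frames(paths, spacing_mm_per_px: float):
    """Load grayscale PNG/TIFF images back as :class:`BModeFrame` objects."""
    import imageio.v3 as iio

    frames = []
    for i, path in enumerate(paths):
        pixels = np.asarray(iio.imread(path))
        if pixels.ndim == 3:
            frames.append(
                DopplerXPlaneFrame(
                    cross_section=pixels,
                    longitudinal=pixels,
                    spacing_mm_per_px=spacing_mm_per_px,
                    timestamp_s=float(i),
                )
            )
        else:
            frames.append(
                BModeFrame(pixels=pixels, spacing_mm_per_px=spacing_mm_per_px, timestamp_s=float(i))
            )
    return frames


def write_ground_truth_csv(path, records) -> None:
    """Ground-truth sidecar: frame_index, x_px, y_px, pose 4x4 row-major."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["frame_index", "x_px", "y_px"] + [f"pose_{i}{j}" for i in range(4) for j in range(4)]
        writer.writerow(header)
        for idx, center, pose in records:
            cx, cy = (center if center is not None else (np.nan, np.nan))
            writer.writerow([idx, cx, cy] + [f"{v:.9g}" for v in np.asarray(pose.matrix).ravel()])
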