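"""Synthetic stand-ins for every hardware input of the training system.

Three generators, all bit-reproducible under fixed seeds:

* :func:`render_scene` — camera frames containing perspective-projected
  fiducial markers at known 6-DoF poses over flat, noise, or textured
  backgrounds, with scripted rectangular occluders; ground-truth poses
  and corner projections are emitted alongside so detector and pose
  accuracy are measurable to sub-pixel level.  Rendering supersamples
  8x with bilinear pattern sampling and box-downsamples, so edges are
  antialiased with continuous coverage and the analytic corner ground
  truth is meaningful well below one pixel.
* :func:`generate_keypoints` — smooth articulated 3-D trajectories of the
  four tracked joints (left shoulder, left elbow, left hand, right hand)
  in the body-tracking basis, with constant segment lengths before
  optional i.i.d. Gaussian noise.
* :func:`generate_atlas` — a procedural ultrasound-like frame atlas on
  the full acquisition grid; every image carries a machine-readable bit
  strip encoding its own (u, v, a) key so selection correctness can be
  asserted from pixels alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .atlas import DOPPLER, AtlasGrid, DopplerClip, FrameKey, frame_path, \
    save_manifest
from .camera_pose import CameraIntrinsics, MarkerGeometry, Pose, project
from .marker_codec import MarkerDictionary, encode

__all__ = [
    "MarkerTrack",
    "Occlusion",
    "SceneScript",
    "FrameTruth",
    "KeypointConfig",
    "KeypointStream",
    "render_scene",
    "generate_keypoints",
    "generate_atlas",
    "decode_frame_key_strip",
    "make_pose",
]

SUPERSAMPLE = 8


def make_pose(tilt_deg: float = 0.0, spin_deg: float = 0.0,
              azimuth_deg: float = 0.0, position=(0.0, 0.0, 0.6)) -> Pose:
    """Marker pose from view angles: out-of-plane tilt about an axis at
    ``azimuth`` in the marker plane, then in-plane spin, at ``position``."""
    axis = Rotation.from_euler("z", azimuth_deg, degrees=True).apply(
        [1.0, 0.0, 0.0])
    R = (Rotation.from_rotvec(np.radians(tilt_deg) * axis)
         * Rotation.from_euler("z", spin_deg, degrees=True)).as_matrix()
    return Pose(rotation=R, translation=np.asarray(position, float))


@dataclass(frozen=True)
class MarkerTrack:
    """One marker's identity, physical size, and pose per frame."""

    marker_id: int
    side_length: float
    poses: tuple[Pose, ...]


@dataclass(frozen=True)
class Occlusion:
    """Opaque rectangle drawn over frames in [start, stop) (half-open)."""

    start: int
    stop: int
    rect: tuple[int, int, int, int]  # x0, y0, x1, y1 (pixels)
    value: int = 128


@dataclass(frozen=True)
class SceneScript:
    """Deterministic description of a rendered camera sequence."""

    intrinsics: CameraIntrinsics
    image_size: tuple[int, int]  # (width, height)
    tracks: tuple[MarkerTrack, ...]
    n_frames: int
    background: str = "flat"  # flat | noise | texture
    occlusions: tuple[Occlusion, ...] = field(default=())
    seed: int = 0
    background_level: int = 200

    def __post_init__(self):
        if self.background not in ("flat", "noise", "texture"):
            raise ValueError(f"unknown background {self.background!r}")
        for tr in self.tracks:
            if len(tr.poses) != self.n_frames:
                raise ValueError("marker track length must equal n_frames")


@dataclass(frozen=True)
class FrameTruth:
    """Ground truth for one rendered frame."""

    poses: dict[int, Pose]           # marker id -> true pose
    corners: dict[int, np.ndarray]   # marker id -> (4, 2) projected corners
    occluded: bool


def _background(script: SceneScript, rng: np.random.Generator) -> np.ndarray:
    w, h = script.image_size
    if script.background == "flat":
        return np.full((h, w), float(script.background_level))
    if script.background == "noise":
        return rng.uniform(0, 255, size=(h, w))
    # texture: coarse seeded noise smoothly upsampled (Perlin-style clutter)
    coarse = rng.uniform(60, 220, size=(h // 16 + 2, w // 16 + 2))
    tex = ndimage.zoom(coarse, 16, order=3)[:h, :w]
    return np.clip(tex, 0, 255)


PATTERN_UPSAMPLE = 16  # marker-image pixels per cell


def _marker_pattern(dictionary: MarkerDictionary, marker_id: int
                    ) -> np.ndarray:
    """Upsampled marker image including a 1-cell white quiet zone.

    The warp samples this image bilinearly, so edge coverage in the
    rendered frame varies continuously with sub-pixel marker position
    (no staircase quantization of the corner ground truth).
    """
    bordered = encode(marker_id, dictionary).bits
    cells = bordered.shape[0]
    pattern = np.full((cells + 2, cells + 2), 255.0)
    pattern[1:-1, 1:-1] = np.where(bordered, 0.0, 255.0)
    k = PATTERN_UPSAMPLE
    return np.kron(pattern, np.ones((k, k)))


def _render_marker_into(image: np.ndarray, pattern: np.ndarray,
                        side_length: float, pose: Pose,
                        intrinsics: CameraIntrinsics) -> None:
    """Composite one marker into the 1x image in place.

    Only the marker's projected bounding box is rasterized, at
    ``SUPERSAMPLE``x resolution, then box-downsampled into the image,
    so edges are antialiased without supersampling the whole frame.
    """
    ss = SUPERSAMPLE
    h, w = image.shape
    k = PATTERN_UPSAMPLE
    cells = pattern.shape[0] // k  # bordered grid + quiet zone, in cells
    cell_m = side_length / (cells - 2)  # marker side spans the bordered grid
    extent = cells * cell_m / 2.0  # half-extent including the quiet zone
    # supersampled intrinsics: 1x pixel u maps to ss*u + (ss-1)/2
    K = np.array([[intrinsics.fx * ss, 0, intrinsics.cx * ss + (ss - 1) / 2],
                  [0, intrinsics.fy * ss, intrinsics.cy * ss + (ss - 1) / 2],
                  [0, 0, 1.0]])
    R, t = pose.rotation, pose.translation
    H = K @ np.column_stack([R[:, 0], R[:, 1], t])
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return
    # bounding box of the projected quiet-zone quad
    quad3d = np.array([[-extent, -extent, 0], [-extent, extent, 0],
                       [extent, extent, 0], [extent, -extent, 0]])
    cam = quad3d @ R.T + t
    if np.any(cam[:, 2] <= 1e-6):
        raise ValueError("marker behind the camera in an unoccluded frame")
    proj = (quad3d[:, :2] @ H[:, :2].T + H[:, 2]).T
    px = proj[0] / proj[2] / ss
    py = proj[1] / proj[2] / ss
    # 1x-pixel bounding box of the projected quiet-zone quad
    bx0 = max(int(np.floor(px.min())) - 1, 0)
    bx1 = min(int(np.ceil(px.max())) + 2, w)
    by0 = max(int(np.floor(py.min())) - 1, 0)
    by1 = min(int(np.ceil(py.max())) + 2, h)
    if bx0 >= bx1 or by0 >= by1:
        return
    # supersampled lattice covering the box
    xs = np.arange(bx0 * ss, bx1 * ss)
    ys = np.arange(by0 * ss, by1 * ss)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
    mk = Hinv @ pts
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = mk[0] / mk[2]
        my = mk[1] / mk[2]
    inside = (np.abs(mx) < extent) & (np.abs(my) < extent) & np.isfinite(mx)
    if not inside.any():
        return
    # start from the (smooth) background so downsampling is exact there
    patch = np.repeat(np.repeat(image[by0:by1, bx0:bx1], ss, axis=0),
                      ss, axis=1)
    # bilinear sample of the upsampled marker image (continuous coverage)
    px_m = (mx[inside] + extent) / cell_m * k - 0.5
    py_m = (my[inside] + extent) / cell_m * k - 0.5
    n_img = cells * k
    x0i = np.clip(np.floor(px_m).astype(int), 0, n_img - 2)
    y0i = np.clip(np.floor(py_m).astype(int), 0, n_img - 2)
    fx = np.clip(px_m - x0i, 0.0, 1.0)
    fy = np.clip(py_m - y0i, 0.0, 1.0)
    vals = (pattern[y0i, x0i] * (1 - fx) * (1 - fy)
            + pattern[y0i, x0i + 1] * fx * (1 - fy)
            + pattern[y0i + 1, x0i] * (1 - fx) * fy
            + pattern[y0i + 1, x0i + 1] * fx * fy)
    flat = patch.ravel()
    flat[inside] = vals
    patch = flat.reshape(patch.shape)
    down = patch.reshape(by1 - by0, ss, bx1 - bx0, ss).mean(axis=(1, 3))
    image[by0:by1, bx0:bx1] = down


def render_scene(script: SceneScript, dictionary: MarkerDictionary
                 ) -> tuple[list[np.ndarray], list[FrameTruth]]:
    """Render all frames of a script; returns (frames, ground truth).

    Frames are uint8 grayscale ``(height, width)``.  Ground truth carries
    the scripted pose and the analytically projected marker corners for
    every marker, plus whether any occluder was active on the frame.
    """
    rng = np.random.default_rng(script.seed)
    patterns = {tr.marker_id: _marker_pattern(dictionary, tr.marker_id)
                for tr in script.tracks}
    frames: list[np.ndarray] = []
    truths: list[FrameTruth] = []
    for f in range(script.n_frames):
        img = _background(script, rng)
        poses: dict[int, Pose] = {}
        corners: dict[int, np.ndarray] = {}
        for tr in script.tracks:
            pose = tr.poses[f]
            _render_marker_into(img, patterns[tr.marker_id],
                                tr.side_length, pose, script.intrinsics)
            poses[tr.marker_id] = pose
            geom = MarkerGeometry(side_length=tr.side_length)
            corners[tr.marker_id] = project(geom.corners, pose,
                                            script.intrinsics)
        occluded = False
        for occ in script.occlusions:
            if occ.start <= f < occ.stop:
                x0, y0, x1, y1 = occ.rect
                img[y0:y1, x0:x1] = occ.value
                occluded = True
        frames.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
        truths.append(FrameTruth(poses=poses, corners=corners,
                                 occluded=occluded))
    return frames, truths


# -- body keypoints -------------------------------------------------------

JOINTS = ("left_shoulder", "left_elbow", "left_hand", "right_hand")


@dataclass(frozen=True)
class KeypointConfig:
    """Articulated-arm trajectory parameters (body-tracking basis, metres).

    The left arm hangs from a fixed shoulder; elbow and hand follow
    smooth seeded joint-angle splines with constant segment lengths
    (upper arm and forearm).  The right hand moves on its own smooth
    track.  ``sigma`` metres of i.i.d. Gaussian noise is added per frame
    per coordinate after the noise-free kinematics.
    """

    n_frames: int = 300
    fps: float = 30.0
    sigma: float = 0.0
    seed: int = 0
    shoulder: tuple[float, float, float] = (0.0, 1.4, 0.0)
    upper_arm_length: float = 0.30
    forearm_length: float = 0.27
    n_spline_knots: int = 6


@dataclass(frozen=True)
class KeypointStream:
    """Per-frame joint positions; (n_frames, 3) array per joint name."""

    positions: dict[str, np.ndarray]
    noise_free: dict[str, np.ndarray]
    fps: float
    sigma: float
    seed: int

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    def at(self, frame: int) -> dict[str, np.ndarray]:
        return {j: self.positions[j][frame] for j in self.positions}


def _angle_splines(rng: np.random.Generator, n_knots: int, n_frames: int,
                   lo: float, hi: float) -> np.ndarray:
    knots_t = np.linspace(0, n_frames - 1, n_knots)
    knots_v = rng.uniform(lo, hi, size=n_knots)
    return CubicSpline(knots_t, knots_v)(np.arange(n_frames))


def generate_keypoints(config: KeypointConfig) -> KeypointStream:
    """Smooth articulated keypoint stream; deterministic given the seed."""
    if config.sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    shoulder = np.tile(np.asarray(config.shoulder, float), (n, 1))
    # upper-arm direction from two smooth spherical angles
    theta = np.radians(_angle_splines(rng, config.n_spline_knots, n, 60, 120))
    phi = np.radians(_angle_splines(rng, config.n_spline_knots, n, -30, 30))
    upper = np.column_stack([np.sin(theta) * np.cos(phi),
                             -np.cos(theta),
                             np.sin(theta) * np.sin(phi)])
    elbow = shoulder + config.upper_arm_length * upper
    theta2 = np.radians(_angle_splines(rng, config.n_spline_knots, n, 40, 140))
    phi2 = np.radians(_angle_splines(rng, config.n_spline_knots, n, -40, 40))
    fore = np.column_stack([np.sin(theta2) * np.cos(phi2),
                            -np.cos(theta2),
                            np.sin(theta2) * np.sin(phi2)])
    hand = elbow + config.forearm_length * fore
    rh_center = np.asarray(config.shoulder, float) + np.array([0.45, -0.5, 0.1])
    rh = rh_center + 0.05 * np.column_stack([
        _angle_splines(rng, config.n_spline_knots, n, -1, 1)
        for _ in range(3)])
    noise_free = {"left_shoulder": shoulder, "left_elbow": elbow,
                  "left_hand": hand, "right_hand": rh}
    if config.sigma > 0:
        positions = {j: noise_free[j]
                     + rng.normal(0, config.sigma, size=(n, 3))
                     for j in JOINTS}
    else:
        positions = {j: noise_free[j].copy() for j in JOINTS}
    return KeypointStream(positions=positions, noise_free=noise_free,
                          fps=config.fps, sigma=config.sigma,
                          seed=config.seed)


# -- procedural atlas -----------------------------------------------------

STRIP_BITS = 16  # u-1 in 6 bits, v-1 in 4 bits, a-1 in 6 bits
STRIP_ROWS = 4


def _key_bits(u: int, v: int, a: int) -> list[int]:
    word = ((u - 1) << 10) | ((v - 1) << 6) | (a - 1)
    return [(word >> (STRIP_BITS - 1 - k)) & 1 for k in range(STRIP_BITS)]


def decode_frame_key_strip(image: np.ndarray) -> tuple[int, int, int]:
    """Recover (u, v, a) from the bit strip embedded in an atlas frame."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    w = img.shape[1]
    block = w // STRIP_BITS
    strip = img[:STRIP_ROWS]
    bits = [int(strip[:, k * block:(k + 1) * block].mean() < 128)
            for k in range(STRIP_BITS)]
    word = 0
    for b in bits:
        word = (word << 1) | b
    return ((word >> 10) + 1, ((word >> 6) & 0xF) + 1, (word & 0x3F) + 1)


def _atlas_image(key: FrameKey, size: tuple[int, int],
                 rng: np.random.Generator) -> np.ndarray:
    w, h = size
    yy, xx = np.mgrid[0:h, 0:w]
    # position-dependent band pattern: frequency from u, phase from v,
    # orientation from the sweep index
    ang = np.radians((key.a - 1) * 3.0)
    coord = xx * np.cos(ang) + yy * np.sin(ang)
    img = 128 + 90 * np.sin(2 * np.pi * coord * (0.02 + 0.004 * key.u)
                            + 0.6 * key.v)
    img = np.clip(img, 0, 255)
    block = w // STRIP_BITS
    bits = _key_bits(key.u, key.v, key.a)
    for k, b in enumerate(bits):
        img[:STRIP_ROWS, k * block:(k + 1) * block] = 0 if b else 255
    if key.mode == DOPPLER:
        # seeded time-varying speckle in red/blue flow channels
        speckle = rng.uniform(0, 255, size=(h, w))
        rgb = np.stack([np.where(speckle > 170, speckle, img),
                        img,
                        np.where(speckle < 85, 255 - speckle, img)], axis=2)
        rgb[:STRIP_ROWS] = img[:STRIP_ROWS, :, None]
        return np.clip(rgb, 0, 255).astype(np.uint8)
    return img.astype(np.uint8)


def generate_atlas(grid: AtlasGrid, seed: int, out_dir,
                   image_size: tuple[int, int] = (32, 32),
                   clip_fps: float = 15.0, clip_duration_s: float = 10.0
                   ) -> Path:
    """Write a procedural atlas under ``out_dir``; returns the manifest path.

    One PNG per (mode, u, v, a) key plus, for Doppler, two clips of
    ``clip_duration_s`` seconds at ``clip_fps`` stored as per-frame PNGs
    under ``<out_dir>/doppler/clips/clip{N}/``.  Deterministic for a
    fixed seed.
    """
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    for mode in grid.modes:
        (out / mode).mkdir(parents=True, exist_ok=True)
        for key in grid.keys(mode):
            img = _atlas_image(key, image_size, rng)
            Image.fromarray(img).save(frame_path(out, key))
    clips = []
    if DOPPLER in grid.modes:
        n_clip_frames = int(round(clip_fps * clip_duration_s))
        clip_keys = [
            FrameKey(mode=DOPPLER, u=max(1, grid.n_long // 3),
                     v=max(1, grid.n_lat // 2), a=max(1, grid.n_sweep // 2)),
            FrameKey(mode=DOPPLER, u=max(1, 2 * grid.n_long // 3),
                     v=max(1, grid.n_lat // 2), a=max(1, grid.n_sweep // 2)),
        ]
        for ci, key in enumerate(clip_keys, start=1):
            cdir = out / DOPPLER / "clips" / f"clip{ci}"
            cdir.mkdir(parents=True, exist_ok=True)
            for f in range(n_clip_frames):
                img = _atlas_image(key, image_size, rng)
                Image.fromarray(img).save(cdir / f"f{f:04d}.png")
            clips.append(DopplerClip(
                key=key, path=str(cdir.relative_to(out)), fps=clip_fps,
                duration_s=clip_duration_s))
    full = AtlasGrid(n_long=grid.n_long, n_lat=grid.n_lat,
                     n_sweep=grid.n_sweep, beta_deg=grid.beta_deg,
                     modes=grid.modes, clips=tuple(clips))
    manifest = save_manifest(full, out / "manifest.json")
    run_record = {"seed": seed, "image_size": list(image_size),
                  "clip_fps": clip_fps, "clip_duration_s": clip_duration_s}
    (out / "run.json").write_text(json.dumps(run_record, indent=2))
    return manifest
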