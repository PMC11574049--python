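"""Seeded synthetic two-channel image generation with known ground truth.

Produces curvilinear "fiber" masks, a fiber channel and a spot channel with
controlled amplitudes and Gaussian noise, plus simulated multi-rater
annotations with known sensitivity/specificity. Everything is a pure
function of (spec, seed).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.interpolate import splev, splprep
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import line
from skimage.morphology import disk

from .imaging_io import DEFAULT_PIXEL_SIZE_UM, BinaryMask, ChannelImage

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RaterSimSpec",
    "generate_fiber_mask",
    "place_spots",
    "make_ground_truth",
    "render_image",
    "simulate_rater",
    "generate_dataset",
    "child_seed",
]

MAX_INTENSITY = 65535


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic two-channel image."""

    image_shape: tuple[int, int] = (256, 256)
    n_fibers: int = 3
    fiber_thickness_px: int = 5
    fiber_amplitude: float = 3000.0
    n_puncta_on: int = 10
    n_puncta_off: int = 5
    punctum_sigma_px: float = 1.5
    punctum_amplitude: float = 1000.0
    background_level: float = 50.0
    noise_sd: float = 10.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        self.image_shape = tuple(int(v) for v in self.image_shape)
        if self.n_fibers < 0 or self.n_puncta_on < 0 or self.n_puncta_off < 0:
            raise ValueError("counts must be non-negative")
        if self.fiber_thickness_px < 1:
            raise ValueError("fiber_thickness_px must be positive")
        if self.punctum_sigma_px <= 0:
            raise ValueError("punctum_sigma_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if max(self.fiber_amplitude, self.punctum_amplitude) + self.background_level > MAX_INTENSITY:
            raise ValueError("amplitude + background exceeds 16-bit range")
        if self.n_fibers == 0 and self.n_puncta_on > 0:
            raise ValueError("cannot place on-fiber puncta with n_fibers = 0")

    @property
    def min_separation_px(self) -> int:
        # separation guarantees planted count == resolvable count
        return max(3, math.ceil(4 * self.punctum_sigma_px))


@dataclass
class GroundTruth:
    """A fiber mask plus planted spot records for one synthetic image."""

    fiber_mask: BinaryMask
    spots: list[tuple[int, int, bool, float]]  # (y, x, on_fiber, amplitude)
    spec: SyntheticSpec

    def validate(self) -> None:
        m = self.fiber_mask.pixels
        for y, x, on_fiber, _ in self.spots:
            if bool(m[y, x]) != bool(on_fiber):
                raise AssertionError(f"spot ({y},{x}) violates on_fiber={on_fiber}")


@dataclass
class RaterSimSpec:
    """Error model of one simulated expert annotator."""

    sensitivity: float = 0.95
    specificity: float = 0.98
    boundary_jitter_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity <= 1) or not (0 < self.specificity <= 1):
            raise ValueError("sensitivity and specificity must be in (0, 1]")
        if self.boundary_jitter_px < 0:
            raise ValueError("boundary_jitter_px must be non-negative")


def _fiber_path(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Random-walk control points smoothed by a spline; returns (n, 2) y,x points."""
    h, w = shape
    n_ctrl = 6
    start = rng.uniform([0.1 * h, 0.1 * w], [0.9 * h, 0.9 * w])
    angle = rng.uniform(0, 2 * np.pi)
    step = 0.22 * min(h, w)
    pts = [start]
    for _ in range(n_ctrl - 1):
        angle += rng.normal(0, 0.7)
        nxt = pts[-1] + step * np.array([np.sin(angle), np.cos(angle)])
        nxt = np.clip(nxt, [1, 1], [h - 2, w - 2])
        pts.append(nxt)
    pts = np.asarray(pts)
    # spline through control points, densely sampled
    try:
        tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0, k=min(3, len(pts) - 1))
        u = np.linspace(0, 1, 40 * n_ctrl)
        ys, xs = splev(u, tck)
        dense = np.column_stack([ys, xs])
    except Exception:  # degenerate control polygon: fall back to the polyline
        dense = pts
    return np.clip(dense, [0, 0], [h - 1, w - 1])


def generate_fiber_mask(spec: SyntheticSpec) -> BinaryMask:
    """Rasterize ``n_fibers`` smooth curvilinear structures, dilated to thickness."""
    h, w = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_fibers):
        path = _fiber_path(rng, (h, w))
        ipts = np.round(path).astype(int)
        for (y0, x0), (y1, x1) in zip(ipts[:-1], ipts[1:]):
            rr, cc = line(y0, x0, y1, x1)
            canvas[rr, cc] = True
    if spec.n_fibers and spec.fiber_thickness_px > 1:
        canvas = binary_dilation(canvas, structure=disk(spec.fiber_thickness_px // 2))
    return BinaryMask(pixels=canvas, pixel_size_um=spec.pixel_size_um)


def place_spots(spec: SyntheticSpec, fiber_mask: BinaryMask) -> list[tuple[int, int, bool, float]]:
    """Place spot centers on/off the fiber mask with enforced minimum separation.

    On-fiber centers are drawn from mask-true pixels, off-fiber centers from
    mask-false pixels at least one separation radius away from the mask, so
    neither class can leak across the boundary under detection.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sep = spec.min_separation_px
    h, w = spec.image_shape
    margin = max(2, math.ceil(2 * spec.punctum_sigma_px))

    interior = np.zeros((h, w), dtype=bool)
    interior[margin : h - margin, margin : w - margin] = True
    on_pool = np.argwhere(fiber_mask.pixels & interior)
    off_allowed = ~binary_dilation(fiber_mask.pixels, structure=disk(sep))
    off_pool = np.argwhere(off_allowed & interior)

    placed: list[tuple[int, int, bool, float]] = []

    def try_place(pool: np.ndarray, n: int, on_fiber: bool) -> None:
        if n == 0:
            return
        if len(pool) == 0:
            raise ValueError(f"no candidate pixels to place {'on' if on_fiber else 'off'}-fiber spots")
        order = rng.permutation(len(pool))
        need = n
        for idx in order:
            y, x = int(pool[idx, 0]), int(pool[idx, 1])
            if all((y - py) ** 2 + (x - px) ** 2 >= sep**2 for py, px, _, _ in placed):
                placed.append((y, x, on_fiber, spec.punctum_amplitude))
                need -= 1
                if need == 0:
                    return
        raise ValueError(
            f"could only place {n - need}/{n} {'on' if on_fiber else 'off'}-fiber spots "
            f"at separation {sep}px; reduce counts or enlarge the image"
        )

    try_place(on_pool, spec.n_puncta_on, True)
    try_place(off_pool, spec.n_puncta_off, False)
    return placed


def make_ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Generate mask + spots for a spec; deterministic given ``spec.seed``."""
    mask = generate_fiber_mask(spec)
    spots = place_spots(spec, mask)
    truth = GroundTruth(fiber_mask=mask, spots=spots, spec=spec)
    truth.validate()
    return truth


def render_image(truth: GroundTruth) -> tuple[ChannelImage, ChannelImage]:
    """Render (fiber, spot) channels from ground truth.

    Fiber channel: ``background + fiber_amplitude·mask + N(0, noise_sd)``.
    Spot channel: ``background + Σ spots·exp(-r²/2σ²) + N(0, noise_sd)``,
    with each spot's peak equal to its amplitude at the center pixel.
    Both are clipped to [0, 65535] and stored as uint16.
    """
    spec = truth.spec
    h, w = spec.image_shape
    rng = np.random.default_rng(spec.seed + 2)

    fiber = np.full((h, w), spec.background_level, dtype=np.float64)
    fiber[truth.fiber_mask.pixels] += spec.fiber_amplitude

    spotch = np.full((h, w), spec.background_level, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    radius = math.ceil(4 * spec.punctum_sigma_px)
    for y, x, _, amp in truth.spots:
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        x0, x1 = max(0, x - radius), min(w, x + radius + 1)
        dy = yy[y0:y1, x0:x1] - y
        dx = xx[y0:y1, x0:x1] - x
        spotch[y0:y1, x0:x1] += amp * np.exp(
            -(dy**2 + dx**2) / (2 * spec.punctum_sigma_px**2)
        )

    if spec.noise_sd > 0:
        fiber += rng.normal(0, spec.noise_sd, size=(h, w))
        spotch += rng.normal(0, spec.noise_sd, size=(h, w))

    fiber = np.clip(np.rint(fiber), 0, MAX_INTENSITY).astype(np.uint16)
    spotch = np.clip(np.rint(spotch), 0, MAX_INTENSITY).astype(np.uint16)
    return (
        ChannelImage(fiber, channel_name="PGP9.5", pixel_size_um=spec.pixel_size_um),
        ChannelImage(spotch, channel_name="TRPV1", pixel_size_um=spec.pixel_size_um),
    )


def simulate_rater(truth_mask: BinaryMask, rspec: RaterSimSpec) -> BinaryMask:
    """Corrupt a truth mask with a rater's error model.

    Each true pixel is retained with probability ``sensitivity``; each false
    pixel is flipped with probability ``1 - specificity`` (i.i.d.), after an
    optional random boundary dilation/erosion of up to ``boundary_jitter_px``.
    """
    rng = np.random.default_rng(rspec.seed)
    base = truth_mask.pixels.copy()
    if rspec.boundary_jitter_px > 0:
        r = int(rng.integers(1, rspec.boundary_jitter_px + 1))
        if rng.random() < 0.5:
            base = binary_dilation(base, structure=disk(r))
        else:
            base = binary_erosion(base, structure=disk(r))
    u = rng.random(base.shape)
    out = np.where(base, u < rspec.sensitivity, u >= rspec.specificity)
    return BinaryMask(pixels=out, pixel_size_um=truth_mask.pixel_size_um)


def child_seed(master_seed: int, index: int) -> int:
    """Counter scheme for per-image seeds: SeedSequence([master, index])."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def generate_dataset(
    specs: list[SyntheticSpec],
    out_dir: str | Path,
    master_seed: int | None = None,
) -> dict:
    """Write a dataset (channel TIFFs, truth masks, spot CSVs) plus a JSON manifest.

    If ``master_seed`` is given, each spec's seed is replaced by
    ``child_seed(master_seed, i)``; otherwise specs keep their own seeds.
    Re-running with the same manifest reproduces byte-identical rasters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = []
    for i, spec in enumerate(specs):
        if master_seed is not None:
            spec = SyntheticSpec(**{**asdict(spec), "seed": child_seed(master_seed, i)})
        truth = make_ground_truth(spec)
        fiber_img, spot_img = render_image(truth)
        image_id = f"img{i:04d}"
        paths = {
            "pgp95": f"{image_id}_pgp95.tif",
            "trpv1": f"{image_id}_trpv1.tif",
            "truth_mask": f"{image_id}_mask.tif",
            "spots": f"{image_id}_spots.csv",
        }
        tifffile.imwrite(out_dir / paths["pgp95"], fiber_img.pixels)
        tifffile.imwrite(out_dir / paths["trpv1"], spot_img.pixels)
        tifffile.imwrite(
            out_dir / paths["truth_mask"], truth.fiber_mask.pixels.astype(np.uint8) * 255
        )
        with open(out_dir / paths["spots"], "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["y", "x", "on_fiber", "amplitude"])
            for y, x, on_fiber, amp in truth.spots:
                writer.writerow([y, x, int(on_fiber), amp])
        spec_dict = asdict(spec)
        spec_dict["image_shape"] = list(spec.image_shape)
        images.append(
            {
                "image_id": image_id,
                "seed": spec.seed,
                "spec": spec_dict,
                "files": paths,
                "n_puncta_on": spec.n_puncta_on,
                "n_puncta_off": spec.n_puncta_off,
            }
        )
    manifest = {
        "schema": "punctafiber-manifest-v1",
        "master_seed": master_seed,
        "n_images": len(images),
        "images": images,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def dataset_hashes(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every raster/CSV referenced by a dataset manifest."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    hashes: dict[str, str] = {}
    for rec in manifest["images"]:
        for name in sorted(rec["files"].values()):
            hashes[name] = hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
    return hashes
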