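"""Trainable pixel-classification segmentation of fiber structures.

A fixed multi-scale feature bank (Gaussian, gradient magnitude, Laplacian
of Gaussian, the two Hessian eigenvalues, and difference-of-Gaussians at
each scale, plus the raw image) feeds a random-forest pixel classifier.
An "external mask" backend wraps precomputed masks (e.g. from a separately
trained deep model) behind the same interface, since everything downstream
of segmentation is identical for both routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.measure import label as cc_label
from sklearn.ensemble import RandomForestClassifier

from .imaging_io import BinaryMask, ChannelImage

__all__ = [
    "DEFAULT_SCALES",
    "FEATURE_KINDS",
    "FeatureStack",
    "PixelClassifier",
    "SegmentationResult",
    "compute_features",
    "train_classifier",
    "predict_probability",
    "postprocess_mask",
    "segment",
    "save_classifier",
    "load_classifier",
]

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0, 16.0)
FEATURE_KINDS = ("gaussian", "gradient_magnitude", "log", "hessian_eig0", "hessian_eig1", "dog")
_FORMAT_VERSION = 1


@dataclass
class FeatureStack:
    """(n_features, y, x) real-valued per-pixel features."""

    features: np.ndarray
    feature_names: list[str]
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.features.ndim != 3:
            raise ValueError("features must be 3-D (n_features, y, x)")
        if len(self.feature_names) != self.features.shape[0]:
            raise ValueError("feature_names length mismatch")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite feature values")

    def as_matrix(self) -> np.ndarray:
        """(n_pixels, n_features) design matrix."""
        return self.features.reshape(self.features.shape[0], -1).T


@dataclass
class PixelClassifier:
    """Fitted tree ensemble plus the feature configuration it expects."""

    model: RandomForestClassifier
    scales: tuple[float, ...] = DEFAULT_SCALES
    class_labels: tuple[str, str] = ("background", "fiber")

    @property
    def n_features(self) -> int:
        return len(self.scales) * len(FEATURE_KINDS) + 1


@dataclass
class SegmentationResult:
    probability: np.ndarray
    mask: BinaryMask
    backend_name: str


def compute_features(
    image: ChannelImage, scales: tuple[float, ...] | list[float] = DEFAULT_SCALES
) -> FeatureStack:
    """Multi-scale feature bank; n_features = 6 * n_scales + 1 (raw intensity)."""
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if list(scales) != sorted(scales):
        raise ValueError("scales must be ascending")
    img = np.asarray(image.pixels, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("compute_features requires a 2-D image")

    feats: list[np.ndarray] = [img]
    names: list[str] = ["raw"]
    # demeaning cancels the truncated-kernel residual of second-derivative
    # filters, so derivative features of a constant image are exactly zero
    centered = img - img.mean()
    for s in scales:
        smooth = ndimage.gaussian_filter(img, sigma=s)
        gy = ndimage.sobel(smooth, axis=0)
        gx = ndimage.sobel(smooth, axis=1)
        grad = np.hypot(gy, gx)
        log_ = ndimage.gaussian_laplace(centered, sigma=s)
        hrr, hrc, hcc = hessian_matrix(
            centered, sigma=s, order="rc", use_gaussian_derivatives=True
        )
        eig0, eig1 = hessian_matrix_eigvals([hrr, hrc, hcc])
        dog = smooth - ndimage.gaussian_filter(img, sigma=2 * s)
        for kind, f in zip(FEATURE_KINDS, (smooth, grad, log_, eig0, eig1, dog)):
            feats.append(f)
            names.append(f"{kind}_s{s:g}")
    return FeatureStack(
        features=np.stack(feats), feature_names=names, source_shape=img.shape
    )


def train_classifier(
    images: list[ChannelImage],
    labels: list[tuple[BinaryMask, BinaryMask]],
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the ensemble on labeled pixels only.

    ``labels[i]`` is a (fiber_strokes, background_strokes) mask pair for
    ``images[i]``; strokes may be sparse scribbles or dense masks. A pixel
    labeled in both classes is an error, as is an empty class overall.
    """
    if len(images) != len(labels):
        raise ValueError("one label pair per image required")
    xs, ys = [], []
    for img, (fiber, bg) in zip(images, labels):
        if fiber.shape != img.shape or bg.shape != img.shape:
            raise ValueError("label raster shape mismatch")
        if (fiber.pixels & bg.pixels).any():
            raise ValueError("pixels labeled as both fiber and background")
        fs = compute_features(img, scales)
        mat = fs.as_matrix()
        sel = fiber.pixels.ravel() | bg.pixels.ravel()
        xs.append(mat[sel])
        ys.append(fiber.pixels.ravel()[sel].astype(np.int8))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("class underrepresented: both fiber and background strokes are required")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(x, y)
    return PixelClassifier(model=model, scales=tuple(scales))


def predict_probability(clf: PixelClassifier, image: ChannelImage) -> np.ndarray:
    """Per-pixel fiber probability (fraction of trees voting fiber), in [0, 1]."""
    fs = compute_features(image, clf.scales)
    if fs.features.shape[0] != getattr(clf.model, "n_features_in_", clf.n_features):
        raise ValueError("feature configuration mismatch between classifier and input")
    proba = clf.model.predict_proba(fs.as_matrix())
    fiber_col = list(clf.model.classes_).index(1)
    return proba[:, fiber_col].reshape(image.shape)


def postprocess_mask(
    probability: np.ndarray,
    threshold: float = 0.5,
    min_object_px: int = 64,
    pixel_size_um: float | None = None,
) -> BinaryMask:
    """Binarize at ``threshold`` (inclusive) and drop 8-connected components
    smaller than ``min_object_px``."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    binary = np.asarray(probability) >= threshold
    if min_object_px > 1 and binary.any():
        lab, n = cc_label(binary, connectivity=2, return_num=True)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_object_px
        keep[0] = False
        binary = keep[lab]
    kwargs = {} if pixel_size_um is None else {"pixel_size_um": pixel_size_um}
    return BinaryMask(pixels=binary, **kwargs)


def segment(
    image: ChannelImage,
    backend: PixelClassifier | BinaryMask,
    threshold: float = 0.5,
    min_object_px: int = 64,
) -> SegmentationResult:
    """Segment an image with either the classifier backend or an external mask.

    An external mask (e.g. produced by a separately trained deep model) is
    wrapped unchanged; its probability raster is the 0/1 mask itself.
    """
    if isinstance(backend, BinaryMask):
        if backend.shape != image.shape:
            raise ValueError("external mask shape does not match image")
        return SegmentationResult(
            probability=backend.pixels.astype(np.float64),
            mask=backend,
            backend_name="external",
        )
    try:
        prob = predict_probability(backend, image)
    except Exception as exc:
        raise RuntimeError(f"segmentation backend failed on {image.channel_name}: {exc}") from exc
    mask = postprocess_mask(
        prob, threshold=threshold, min_object_px=min_object_px, pixel_size_um=image.pixel_size_um
    )
    return SegmentationResult(probability=prob, mask=mask, backend_name="rf")


def save_classifier(clf: PixelClassifier, path) -> None:
    """Serialize classifier + feature configuration to one versioned file."""
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "scales": list(clf.scales),
            "class_labels": list(clf.class_labels),
            "model": clf.model,
        },
        path,
    )


def load_classifier(path) -> PixelClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported classifier file version: {payload.get('format_version')}")
    return PixelClassifier(
        model=payload["model"],
        scales=tuple(payload["scales"]),
        class_labels=tuple(payload["class_labels"]),
    )
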