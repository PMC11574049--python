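"""Per-image quantification: punctum count, mean fluorescence intensity on
fibers (AU), and fiber area (um^2)."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DEFAULT_THRESHOLD, detect_maxima
from .imaging_io import BinaryMask, ChannelImage, read_mask
from .segmentation import SegmentationResult, segment

logger = logging.getLogger(__name__)

__all__ = [
    "QuantRecord",
    "measure_mfi",
    "measure_area",
    "quantify_image",
    "quantify_batch",
    "QUANT_COLUMNS",
]

QUANT_COLUMNS = [
    "image_id",
    "method",
    "n_puncta",
    "mfi_au",
    "fiber_area_um2",
    "threshold",
    "pixel_size_um",
]


@dataclass
class QuantRecord:
    image_id: str
    method: str
    n_puncta: int
    mfi_au: float
    fiber_area_um2: float
    threshold: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.n_puncta < 0 or self.mfi_au < 0 or self.fiber_area_um2 < 0:
            raise ValueError("quantities must be non-negative")


def measure_mfi(channel: ChannelImage, mask: BinaryMask) -> float:
    """Arithmetic mean of channel intensities over mask-true pixels."""
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if not mask.pixels.any():
        raise ValueError("empty fiber mask: MFI undefined")
    return float(np.asarray(channel.pixels, dtype=np.float64)[mask.pixels].mean())


def measure_area(mask: BinaryMask) -> float:
    """Mask area in um^2: true-pixel count x pixel_size_um^2."""
    return mask.area_px() * mask.pixel_size_um**2


def quantify_image(
    trpv1: ChannelImage,
    seg: SegmentationResult,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "rf",
    image_id: str = "",
    connectivity: int = 8,
) -> QuantRecord:
    """Detect maxima in the spot channel restricted to the segmentation mask
    and assemble the per-image record."""
    spots = detect_maxima(
        trpv1, seg.mask, threshold=threshold, connectivity=connectivity, image_id=image_id
    )
    return QuantRecord(
        image_id=image_id,
        method=method,
        n_puncta=len(spots),
        mfi_au=measure_mfi(trpv1, seg.mask),
        fiber_area_um2=measure_area(seg.mask),
        threshold=threshold,
        pixel_size_um=seg.mask.pixel_size_um,
    )


def quantify_batch(
    manifest: dict | str | Path,
    backends: dict,
    threshold: float = DEFAULT_THRESHOLD,
    out_csv: str | Path | None = None,
    base_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Quantify every manifest image with every backend; one row per
    (image, method). Per-image failures are logged and the batch continues.

    ``backends`` maps method name to either a fitted PixelClassifier, the
    string ``"truth"`` (use the manifest's ground-truth mask as an external
    mask), or a callable ``image_id -> BinaryMask``.
    """
    import tifffile

    if not isinstance(manifest, dict):
        manifest_path = Path(manifest)
        base_dir = base_dir or manifest_path.parent
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    if base_dir is None:
        raise ValueError("base_dir required when manifest is passed as a dict")
    base_dir = Path(base_dir)

    rows: list[dict] = []
    failures: list[tuple[str, str, str]] = []
    for rec in manifest["images"]:
        image_id = rec["image_id"]
        try:
            px = rec["spec"].get("pixel_size_um", 0.16)
            trpv1 = ChannelImage(
                tifffile.imread(base_dir / rec["files"]["trpv1"]),
                channel_name="TRPV1",
                pixel_size_um=px,
            )
            pgp95 = ChannelImage(
                tifffile.imread(base_dir / rec["files"]["pgp95"]),
                channel_name="PGP9.5",
                pixel_size_um=px,
            )
        except Exception as exc:  # noqa: BLE001 - batch keeps going
            for method in backends:
                failures.append((image_id, method, str(exc)))
            logger.warning("skipping %s: %s", image_id, exc)
            continue
        for method, backend in backends.items():
            try:
                if backend == "truth":
                    mask = read_mask(
                        base_dir / rec["files"]["truth_mask"], pixel_size_um=px
                    )
                    seg = segment(pgp95, mask)
                elif callable(backend) and not hasattr(backend, "model"):
                    seg = segment(pgp95, backend(image_id))
                else:
                    seg = segment(pgp95, backend)
                rows.append(
                    asdict(
                        quantify_image(
                            trpv1, seg, threshold=threshold, method=method, image_id=image_id
                        )
                    )
                )
            except Exception as exc:  # noqa: BLE001
                failures.append((image_id, method, str(exc)))
                logger.warning("quantification failed for %s/%s: %s", image_id, method, exc)

    table = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    table.attrs["failures"] = failures
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
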