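"""Reading and writing well images and plate artifacts.

Per-well images are 16-bit grayscale TIFF pairs named ``<well>_dapi.tif`` /
``<well>_gfp.tif``; plate maps are the ``well,role,compound,conc,conc_unit``
CSV dialect of :class:`~foxscreen.core.PlateLayout`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .core import ImagePair, PlateLayout

logger = logging.getLogger(__name__)


def write_well_images(directory: str | Path, pairs: Mapping[str, ImagePair]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for well, pair in pairs.items():
        tifffile.imwrite(directory / f"{well}_dapi.tif", np.asarray(pair.dapi, dtype=np.uint16))
        tifffile.imwrite(directory / f"{well}_gfp.tif", np.asarray(pair.gfp, dtype=np.uint16))


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    """Export a label mask as a 16-bit TIFF for visual inspection."""
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_well_images(
    directory: str | Path, layout: PlateLayout
) -> tuple[dict[str, ImagePair], dict[str, str]]:
    """Read the DAPI/GFP TIFF pair of every non-empty well in the layout.

    Returns ``(pairs, flags)``: wells with missing files are flagged and
    skipped (the run continues); a per-well channel shape mismatch is an
    error naming the well. Images come back as float64 so that downstream
    ratios are independent of the on-disk bit depth.
    """
    directory = Path(directory)
    pairs: dict[str, ImagePair] = {}
    flags: dict[str, str] = {}
    for entry in layout.entries():
        if entry.role == "empty":
            continue
        dapi_path = directory / f"{entry.well}_dapi.tif"
        gfp_path = directory / f"{entry.well}_gfp.tif"
        missing = [p.name for p in (dapi_path, gfp_path) if not p.exists()]
        if missing:
            flags[entry.well] = f"missing file(s): {', '.join(missing)}"
            logger.warning("well %s skipped: %s", entry.well, flags[entry.well])
            continue
        dapi = tifffile.imread(dapi_path).astype(np.float64)
        gfp = tifffile.imread(gfp_path).astype(np.float64)
        if dapi.shape != gfp.shape:
            raise ValueError(
                f"well {entry.well}: channel shapes differ ({dapi.shape} vs {gfp.shape})"
            )
        pairs[entry.well] = ImagePair(dapi, gfp)
    return pairs, flags
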