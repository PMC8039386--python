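"""Image, mask and sidecar readers/writers shared by all stages.

Conventions used throughout the package: row-major arrays, 0-based
indices, half-open ranges.  Images are loaded as strictly positive
float grids because the SRAD stage divides by intensity; zero pixels
are raised to a small epsilon with a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

from .errors import GastrolayerError

logger = logging.getLogger("gastrolayer")

#: Replacement value for zero pixels (half of the smallest 8-bit step).
ZERO_EPSILON = 0.5


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF as a 2-D positive float array.

    RGB inputs with identical channels are collapsed to one channel;
    genuinely coloured inputs are rejected as ambiguous.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if np.ptp(arr, axis=2).max() == 0:
            arr = arr[:, :, 0]
        else:
            raise GastrolayerError(f"{path}: colour image is ambiguous, expected grayscale")
    if arr.ndim != 2:
        raise GastrolayerError(f"{path}: expected a 2-D grayscale image")
    out = arr.astype(float)
    n_zero = int((out <= 0).sum())
    if n_zero:
        logger.warning("%s: %d nonpositive pixels raised to %.3g", path, n_zero, ZERO_EPSILON)
        out = np.maximum(out, ZERO_EPSILON)
    return out


def write_image(path, image: np.ndarray) -> None:
    """Write a float image as 16-bit TIFF (.tif) or 8-bit PNG (.png)."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.clip(image, 0, 2**16 - 1).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(np.clip(image, 0, 255).round().astype(np.uint8)).save(path)
    else:
        raise GastrolayerError(f"unsupported image format {path.suffix!r}")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 PNG."""
    m = (np.asarray(mask).astype(bool) * np.uint8(255))
    PILImage.fromarray(m).save(Path(path))


def read_mask(path) -> np.ndarray:
    """Read a 0/255 (or 0/1) PNG mask as a uint8 0/1 array."""
    arr = np.asarray(PILImage.open(Path(path)))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 0).astype(np.uint8)


def write_truth(directory, stem: str, truth) -> None:
    """Write one phantom as image + mask + JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(directory / f"{stem}.tif", truth.image)
    write_mask(directory / f"{stem}_mask.png", truth.wall_mask)
    sidecar = {
        "label": truth.label,
        "proportions": np.asarray(truth.proportions).tolist(),
        "boundary_rows": np.asarray(truth.boundary_rows).tolist(),
        "wall_top": np.asarray(truth.wall_top).tolist(),
        "wall_bottom": np.asarray(truth.wall_bottom).tolist(),
        "seed": None if truth.spec is None else truth.spec.seed,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar))


def read_truth(directory, stem: str):
    """Load a phantom written by :func:`write_truth`."""
    from .phantom import PhantomTruth

    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    return PhantomTruth(
        image=read_image(directory / f"{stem}.tif"),
        wall_mask=read_mask(directory / f"{stem}_mask.png"),
        boundary_rows=np.asarray(meta["boundary_rows"]),
        wall_top=np.asarray(meta["wall_top"]),
        wall_bottom=np.asarray(meta["wall_bottom"]),
        proportions=np.asarray(meta["proportions"]),
        label=meta["label"],
    )


def list_truth_stems(directory) -> list[str]:
    return sorted(p.stem for p in Path(directory).glob("*.json"))
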