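"""TIFF stack reading/writing with acquisition metadata carried in-tag."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import ImageSequence

__all__ = ["read_stack", "write_stack"]


def write_stack(seq: ImageSequence, path, dtype: str = "float32") -> None:
    """Write a multi-page grayscale TIFF (float32 or uint16, flag-selectable).

    pixel size and frame interval travel in the image-description tag as
    JSON, so ``read_stack(write_stack(seq))`` is a lossless round trip for
    float32.
    """
    if dtype not in ("float32", "uint16"):
        raise ValueError("dtype must be 'float32' or 'uint16'")
    frames = seq.frames
    if dtype == "uint16":
        frames = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max)
    data = frames.astype(dtype)
    description = json.dumps({
        "pixel_size_um": seq.pixel_size_um,
        "frame_interval_ms": seq.frame_interval_ms,
        "meta": {k: v for k, v in seq.meta.items()
                 if isinstance(v, (str, int, float, bool))},
    })
    tifffile.imwrite(path, data, photometric="minisblack", description=description)


def read_stack(path) -> ImageSequence:
    """Read a grayscale TIFF stack; single images are promoted to T = 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        description = page.description
        if page.samplesperpixel and page.samplesperpixel > 1:
            raise ValueError(
                f"{path}: RGB/multichannel input is not supported (grayscale only)"
            )
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack, got shape {data.shape} "
            "(RGB/multichannel input is not supported)"
        )
    if data.dtype.kind not in "uif":
        raise ValueError(f"{path}: unsupported dtype {data.dtype}")
    kwargs = {}
    meta = {}
    if description:
        try:
            parsed = json.loads(description)
            kwargs = {
                "pixel_size_um": parsed.get("pixel_size_um", 0.108),
                "frame_interval_ms": parsed.get("frame_interval_ms", 2.0),
            }
            meta = parsed.get("meta", {})
        except (json.JSONDecodeError, AttributeError):
            pass
    return ImageSequence(data.astype(np.float64), meta=meta, **kwargs)
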