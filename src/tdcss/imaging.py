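"""Extraction of per-well secretion signals from time-lapse image stacks.

Each microwell holds one cell; the well's mean fluorescence tracks the
cytokine captured on the surface beneath it.  The secretion signal of a
well is its mean ROI intensity at each frame minus the mean ROI intensity
in the first frame, so every trace starts at exactly zero and remains in
linear (background-referenced) units.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .errors import ROIError, SchemaError
from .trace import SecretionTrace

__all__ = ["disk_mask", "extract_well_signals", "read_stack", "write_stack"]


def read_stack(path) -> np.ndarray:
    """Read a multi-frame TIFF stack as a (frame, y, x) array."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frame, y, x) array as a multi-frame TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of a disk well at ``center`` (row, col) with ``radius`` px."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def extract_well_signals(
    image_stack: np.ndarray,
    well_rois: Mapping[str, np.ndarray],
    times: np.ndarray,
    channel: str = "ch1",
) -> list[SecretionTrace]:
    """Turn an image stack plus well ROI masks into secretion traces.

    Parameters
    ----------
    image_stack : ndarray, shape (frames, y, x)
        Time-lapse intensity stack, one frame per scan.
    well_rois : mapping of cell id -> boolean mask, shape (y, x)
        Pixel masks of the wells; every mask must be non-empty and within
        the frame bounds.
    times : ndarray of float
        Hours since stimulation for each frame.

    Returns
    -------
    list of SecretionTrace
        ``signal[k]`` is the ROI mean at frame ``k`` minus the ROI mean at
        frame 0 (hence ``signal[0] == 0``).
    """
    stack = np.asarray(image_stack)
    if stack.ndim != 3:
        raise SchemaError(f"image stack must be 3-D (frame, y, x), got {stack.ndim}-D")
    if stack.shape[0] < 2:
        raise SchemaError("image stack needs at least 2 frames")
    times = np.asarray(times, dtype=float)
    if times.size != stack.shape[0]:
        raise SchemaError(
            f"{stack.shape[0]} frames but {times.size} time points"
        )

    traces = []
    for cell_id, mask in well_rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[1:]:
            raise ROIError(
                f"ROI for {cell_id} has shape {mask.shape}, frame is {stack.shape[1:]}"
            )
        if not mask.any():
            raise ROIError(f"ROI for {cell_id} is empty")
        means = stack[:, mask].mean(axis=1)
        traces.append(
            SecretionTrace(
                cell_id=str(cell_id),
                times=times,
                signal=means - means[0],
                channel=channel,
            )
        )
    return traces
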