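"""Molecule detection, kymograph construction, and per-molecule summaries.

The workflow mirrors standard nanochannel analysis: detect molecules in
the time-averaged image, cut a kymograph (position x time) for each,
locate the molecule edges in every frame at half of the intensity plateau
with subpixel interpolation, and summarize each molecule by its
time-averaged extension, the standard deviation of the extension over
frames, and the background-adjusted mean emission intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "Kymograph",
    "SegmentBox",
    "EdgeTrack",
    "MoleculeSummary",
    "detect_molecules",
    "build_kymograph",
    "extract_edges",
    "summarize_molecule",
    "read_stack",
]


@dataclass
class ImageStack:
    """Multi-frame image stack: frames indexed (time, row, column)."""

    frames: np.ndarray
    pixel_size: float        # nm / pixel
    frame_interval: float    # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (time, rows, cols) array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SegmentBox:
    """A detected molecule segment on one channel line."""

    row: int
    col_start: int           # inclusive, already padded
    col_stop: int            # exclusive
    flags: list = field(default_factory=list)


@dataclass
class Kymograph:
    """Position x time intensity matrix for one molecule."""

    matrix: np.ndarray       # (positions, frames)
    channel_index: int
    origin: tuple            # (row, col_start) in the source stack
    pixel_size: float        # nm
    frame_interval: float    # s

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EdgeTrack:
    """Per-frame molecule edges in um, with missing/split bookkeeping."""

    left_um: np.ndarray
    right_um: np.ndarray
    missing: np.ndarray      # bool per frame: no usable signal
    split: np.ndarray        # bool per frame: >= 2 separated segments

    @property
    def extension_um(self) -> np.ndarray:
        return self.right_um - self.left_um


@dataclass
class MoleculeSummary:
    molecule_id: int
    extension_um: float          # time-average of per-frame extension
    extension_sd_um: float       # population SD over frames
    mean_intensity: float        # background-adjusted camera units
    n_frames_used: int


def detect_molecules(
    stack: ImageStack,
    min_length_px: int = 10,
    snr_threshold: float = 5.0,
    pad_px: int = 8,
    transverse_half_width: int = 1,
    max_length_px: int | None = None,
) -> list[SegmentBox]:
    """Detect molecule segments in the time-averaged stack.

    Channel lines are found as peaks of the transverse (row-wise) profile
    of the time average; each line's 1-D longitudinal profile is summed
    over ``transverse_half_width`` rows, and contiguous runs exceeding
    background + ``snr_threshold`` * noise-SD for at least
    ``min_length_px`` pixels become boxes, padded by ``pad_px``.

    Boxes much longer than expected are flagged ``"suspect_merge"``:
    explicitly when ``max_length_px`` is given, otherwise when a box
    exceeds 1.6x the median detected length (>= 3 detections).
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    avg = stack.frames.mean(axis=0)
    row_profile = avg.max(axis=1)
    # channel-line finding is permissive (PSF spread raises most rows above
    # true background); spurious lines are rejected by the run test below
    floor = np.percentile(row_profile, 10)
    lower = row_profile[row_profile <= np.percentile(row_profile, 50)]
    noise = 1.4826 * np.median(np.abs(lower - np.median(lower))) + 1e-12
    peaks, _ = find_peaks(row_profile, height=floor + 5 * noise, distance=2)

    boxes: list[SegmentBox] = []
    run_lengths: list[int] = []
    n_cols = avg.shape[1]
    for row in peaks:
        r0 = max(row - transverse_half_width, 0)
        r1 = min(row + transverse_half_width + 1, avg.shape[0])
        prof = avg[r0:r1].sum(axis=0)
        # background from the lowest quartile: molecules may span half the
        # field of view, which would corrupt a plain median
        low = np.sort(prof)[: max(prof.size // 4, 4)]
        bg = np.median(low)
        sd = 1.4826 * np.median(np.abs(low - bg)) + 1e-12
        above = prof > bg + snr_threshold * sd
        # contiguous runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= min_length_px:
                boxes.append(SegmentBox(
                    row=int(row),
                    col_start=max(start - pad_px, 0),
                    col_stop=min(stop + pad_px, n_cols),
                ))
                run_lengths.append(int(stop - start))
    if max_length_px is not None:
        for b, rl in zip(boxes, run_lengths):
            if rl > max_length_px:
                b.flags.append("suspect_merge")
    elif len(boxes) >= 3:
        med = float(np.median(run_lengths))
        for b, rl in zip(boxes, run_lengths):
            if rl > 1.6 * med:
                b.flags.append("suspect_merge")
    return boxes


def build_kymograph(
    stack: ImageStack,
    box: SegmentBox,
    transverse_half_width: int = 1,
    channel_index: int = 0,
) -> Kymograph:
    """Sum intensity across the channel width per frame and stack columns."""
    r0 = box.row - transverse_half_width
    r1 = box.row + transverse_half_width + 1
    if r0 < 0 or r1 > stack.frames.shape[1] \
            or box.col_start < 0 or box.col_stop > stack.frames.shape[2]:
        raise ValueError("box outside image bounds")
    matrix = stack.frames[:, r0:r1, box.col_start:box.col_stop].sum(axis=1).T
    return Kymograph(matrix=matrix, channel_index=channel_index,
                     origin=(box.row, box.col_start),
                     pixel_size=stack.pixel_size,
                     frame_interval=stack.frame_interval)


def _column_edges(profile: np.ndarray, threshold_fraction: float,
                  flank_px: int, min_gap_px: int):
    """Edges, split flag, background for one kymograph column.

    Background = median of the flanking pixels; plateau = median of
    background-subtracted values at/above half the maximum; edges at the
    outermost crossings of threshold_fraction * plateau, with linear
    subpixel interpolation.  Returns (left, right, n_segments) in pixel
    units, or None if the column has no usable signal.
    """
    n = profile.size
    flank = np.concatenate([profile[:flank_px], profile[-flank_px:]]) \
        if flank_px > 0 and 2 * flank_px < n else profile
    bg = float(np.median(flank))
    p = profile - bg
    peak = p.max()
    if peak <= 0:
        return None
    plateau = float(np.median(p[p >= 0.5 * peak]))
    thr = threshold_fraction * plateau
    above = p > thr
    if not above.any():
        return None
    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]
    # subpixel: interpolate the crossing between bracketing pixels
    if first > 0 and p[first] != p[first - 1]:
        left = first - 1 + (thr - p[first - 1]) / (p[first] - p[first - 1])
    else:
        left = float(first)
    if last < n - 1 and p[last] != p[last + 1]:
        right = last + (thr - p[last]) / (p[last + 1] - p[last])
    else:
        right = float(last)
    # count segments separated by >= min_gap_px below-threshold pixels
    runs = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = runs[::2], runs[1::2]
    n_seg = 1
    for k in range(1, len(starts)):
        if starts[k] - stops[k - 1] >= min_gap_px:
            n_seg += 1
    return left, right, n_seg, bg


def extract_edges(
    kymo: Kymograph,
    threshold_fraction: float = 0.5,
    flank_px: int = 6,
    min_gap_px: int = 2,
) -> EdgeTrack:
    """Per-frame (left, right) molecule edges in um.

    Frames without signal above background are marked missing; frames
    with >= 2 separated above-threshold segments report the edges of the
    union and raise the split flag.  Raises if every frame is missing.
    """
    T = kymo.n_frames
    left = np.full(T, np.nan)
    right = np.full(T, np.nan)
    missing = np.zeros(T, dtype=bool)
    split = np.zeros(T, dtype=bool)
    px_um = kymo.pixel_size / 1000.0
    for t in range(T):
        res = _column_edges(kymo.matrix[:, t], threshold_fraction,
                            flank_px, min_gap_px)
        if res is None:
            missing[t] = True
            continue
        l, r, n_seg, _bg = res
        left[t] = l * px_um
        right[t] = r * px_um
        split[t] = n_seg >= 2
    if missing.all():
        raise ValueError(
            f"no usable frames in kymograph at origin {kymo.origin}"
        )
    return EdgeTrack(left_um=left, right_um=right, missing=missing, split=split)


def summarize_molecule(
    kymo: Kymograph,
    edges: EdgeTrack,
    molecule_id: int = 0,
    threshold_fraction: float = 0.5,
    flank_px: int = 6,
    min_usable_frames: int = 3,
) -> MoleculeSummary:
    """Extension, extension SD, and background-adjusted mean intensity.

    Frames that are missing or split are excluded.  Extension is the mean
    of per-frame (right - left); its SD is the population SD over the used
    frames.  Mean intensity averages the background-subtracted signal over
    time and position between the edges.
    """
    usable = ~edges.missing & ~edges.split
    n_used = int(usable.sum())
    if n_used < min_usable_frames:
        logger.info("molecule %s dropped: only %d usable frames",
                    molecule_id, n_used)
        raise ValueError(
            f"molecule {molecule_id}: {n_used} usable frames "
            f"(minimum {min_usable_frames})"
        )
    ext = edges.extension_um[usable]
    px_um = kymo.pixel_size / 1000.0
    vals = []
    for t in np.flatnonzero(usable):
        profile = kymo.matrix[:, t]
        n = profile.size
        flank = np.concatenate([profile[:flank_px], profile[-flank_px:]]) \
            if flank_px > 0 and 2 * flank_px < n else profile
        bg = float(np.median(flank))
        i0 = int(np.floor(edges.left_um[t] / px_um))
        i1 = int(np.ceil(edges.right_um[t] / px_um)) + 1
        vals.append(np.mean(profile[max(i0, 0):min(i1, n)] - bg))
    return MoleculeSummary(
        molecule_id=molecule_id,
        extension_um=float(np.mean(ext)),
        extension_sd_um=float(np.std(ext)),   # population SD convention
        mean_intensity=float(np.mean(vals)),
        n_frames_used=n_used,
    )


def read_stack(path, pixel_size: float, frame_interval: float) -> ImageStack:
    """Read a multi-frame grayscale TIFF as an ImageStack."""
    import tifffile

    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames, pixel_size=pixel_size,
                      frame_interval=frame_interval)
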