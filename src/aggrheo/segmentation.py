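"""Binarization and multi-pass rough circular Hough segmentation.

Brightfield images of stirred-suspension hiPSC aggregates show dark,
near-circular bodies on a light background.  Segmentation proceeds in two
steps:

1. global thresholding — a pixel is foreground when its normalised
   intensity falls below a threshold chosen in the 0.4-0.6 window;
2. a rough circular Hough transform — every foreground pixel is a
   candidate circle center (A, B); another foreground pixel (x, y) casts a
   vote for radius R at that center when it solves
   (x - A)^2 + (y - B)^2 = R^2 within a half-pixel annulus.  The
   highest-voted (center, radius) combinations become detections; a
   ``sensitivity`` hyperparameter in [0, 1] biases split votes toward
   larger radii.

The full procedure runs five passes with progressively narrower radius
ranges (20-200, 40-200, 60-200, 80-200, 90-200 px) and rising
sensitivities (0.72, 0.76, 0.80, 0.88, 0.92), then stacks the per-pass
detections and discards repeats.

The accumulator here is exact for the votes it reports but only evaluates
candidate centers near local maxima of the foreground distance transform;
centers far from a medial-axis peak cannot out-vote those near one, so
the restriction changes no detection while keeping cost tractable (the
tests compare against a brute-force all-centers accumulator on small
images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import ConfigurationError, ImageFormatError

__all__ = [
    "BinaryImage",
    "HoughPassConfig",
    "AggregateDetection",
    "DEFAULT_PASSES",
    "DEFAULT_THRESHOLD",
    "binarize",
    "hough_detect",
    "multi_pass_segment",
    "dedupe_detections",
]

DEFAULT_THRESHOLD = 0.5

#: Five-pass schedule: radius search bounds (px) and sensitivities.
DEFAULT_PASSES: tuple["HoughPassConfig", ...]


@dataclass(frozen=True)
class HoughPassConfig:
    """Radius search bounds (px) and sensitivity for one Hough pass."""

    radius_min_px: float
    radius_max_px: float
    sensitivity: float

    def __post_init__(self):
        if not 0 < self.radius_min_px < self.radius_max_px:
            raise ConfigurationError("need 0 < radius_min < radius_max")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigurationError("sensitivity must lie in [0, 1]")


DEFAULT_PASSES = (
    HoughPassConfig(20, 200, 0.72),
    HoughPassConfig(40, 200, 0.76),
    HoughPassConfig(60, 200, 0.80),
    HoughPassConfig(80, 200, 0.88),
    HoughPassConfig(90, 200, 0.92),
)


@dataclass(frozen=True)
class BinaryImage:
    """Thresholded field; ``pixels`` is True on the dark (aggregate) phase."""

    pixels: np.ndarray
    threshold_used: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class AggregateDetection:
    """One Hough hit: center (A, B) in (row, col), radius R and its votes."""

    center: tuple[int, int]
    radius_px: float
    votes: int
    pass_index: int = 0


def binarize(
    image: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    allow_out_of_range: bool = False,
) -> BinaryImage:
    """Global threshold: foreground iff intensity / 255 < threshold.

    ``threshold`` is a fraction of full scale and must lie in the
    0.4-0.6 window unless ``allow_out_of_range`` is set.
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.dtype != np.uint8:
        raise ImageFormatError(
            "expected a single-channel 8-bit image, got "
            f"shape {arr.shape} dtype {arr.dtype}"
        )
    if not (0.4 <= threshold <= 0.6) and not allow_out_of_range:
        raise ConfigurationError(
            f"threshold {threshold} outside the 0.4-0.6 window; pass "
            "allow_out_of_range=True to override"
        )
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("threshold must lie strictly in (0, 1)")
    return BinaryImage(
        pixels=arr.astype(float) / 255.0 < threshold,
        threshold_used=float(threshold),
    )


# ---------------------------------------------------------------------------
# accumulator internals


def _vote_profiles(
    fg_rows: np.ndarray,
    fg_cols: np.ndarray,
    centers: np.ndarray,
    r_lo: int,
    r_hi: int,
) -> np.ndarray:
    """Vote counts v[center, R] for integer radii r_lo..r_hi.

    A foreground pixel at distance d votes at R = round(d), i.e. within
    the half-pixel annulus [R - 0.5, R + 0.5).
    """
    n_r = r_hi - r_lo + 1
    votes = np.zeros((len(centers), n_r), dtype=np.int64)
    # chunk candidate centers to bound the broadcast footprint
    chunk = max(1, int(4e6 / max(len(fg_rows), 1)))
    for s in range(0, len(centers), chunk):
        cc = centers[s : s + chunk]
        d = np.hypot(
            fg_rows[None, :] - cc[:, 0:1], fg_cols[None, :] - cc[:, 1:2]
        )
        ridx = np.rint(d).astype(np.int64) - r_lo
        valid = (ridx >= 0) & (ridx < n_r)
        cand_idx = np.broadcast_to(
            np.arange(len(cc))[:, None], ridx.shape
        )
        flat = cand_idx[valid] * n_r + ridx[valid]
        counts = np.bincount(flat, minlength=len(cc) * n_r)
        votes[s : s + chunk] += counts.reshape(len(cc), n_r)
    return votes


def _select_radius(
    profile: np.ndarray, r_lo: int, sensitivity: float, accept_frac: float
) -> tuple[int, int] | None:
    """Apply the acceptance threshold and the split-vote sensitivity rule.

    A radius R is acceptable when its votes cover at least
    ``accept_frac`` of the ideal circle perimeter 2*pi*R.  Among
    acceptable radii, those whose votes reach
    ``(1 - sensitivity) * max_votes`` are split-vote candidates and the
    largest is selected: sensitivity 0 reduces to the pure argmax,
    sensitivity 1 always takes the largest acceptable radius.
    """
    radii = np.arange(r_lo, r_lo + len(profile))
    acceptable = profile >= accept_frac * 2.0 * np.pi * radii
    if not np.any(acceptable):
        return None
    v_acc = np.where(acceptable, profile, -1)
    v_max = int(v_acc.max())
    candidates = np.nonzero(v_acc >= (1.0 - sensitivity) * v_max)[0]
    pick = int(candidates.max())
    return int(radii[pick]), int(profile[pick])


def _circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two disks with center distance d."""
    if d >= r1 + r2:
        return 0.0
    r_small, r_big = min(r1, r2), max(r1, r2)
    if d <= r_big - r_small:
        return np.pi * r_small**2
    a1 = r1**2 * np.arccos(
        np.clip((d**2 + r1**2 - r2**2) / (2 * d * r1), -1, 1)
    )
    a2 = r2**2 * np.arccos(
        np.clip((d**2 + r2**2 - r1**2) / (2 * d * r2), -1, 1)
    )
    k = (
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return float(a1 + a2 - 0.5 * np.sqrt(max(k, 0.0)))


def _is_duplicate(a: AggregateDetection, b: AggregateDetection) -> bool:
    """Two hits describe the same aggregate when their centers nearly
    coincide or the smaller disk lies mostly (>= 60%) inside the larger."""
    d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
    if d < 0.5 * min(a.radius_px, b.radius_px):
        return True
    r_small = min(a.radius_px, b.radius_px)
    overlap = _circle_overlap_area(d, a.radius_px, b.radius_px)
    return overlap >= 0.6 * np.pi * r_small**2


def _detection_order(det: AggregateDetection):
    """Deterministic retention priority: votes, then radius, then earlier
    pass, then raster order."""
    return (-det.votes, -det.radius_px, det.pass_index, det.center)


def dedupe_detections(
    detections: list[AggregateDetection],
) -> list[AggregateDetection]:
    """Discard repeat identifications of the same aggregate.

    Among duplicates the highest-vote detection is retained (ties broken
    toward larger radius, then earlier pass).  Idempotent.
    """
    kept: list[AggregateDetection] = []
    for det in sorted(detections, key=_detection_order):
        if not any(_is_duplicate(det, k) for k in kept):
            kept.append(det)
    return kept


def hough_detect(
    binary: BinaryImage,
    config: HoughPassConfig,
    accept_frac: float = 0.5,
    pass_index: int = 0,
) -> list[AggregateDetection]:
    """One pass of the rough circular Hough transform.

    Votes are accumulated over (A, B, R) for integer radii within the
    pass bounds; a detection needs votes covering at least ``accept_frac``
    of the ideal perimeter 2*pi*R, and split votes are resolved by the
    pass sensitivity (larger radii win as sensitivity approaches 1).
    Overlapping hits from neighbouring candidate centers are collapsed to
    the highest-voted one.  Returned sorted by votes, descending.
    """
    fg = binary.pixels
    h, w = fg.shape
    if config.radius_max_px > min(h, w) / 2:
        raise ConfigurationError(
            f"radius_max {config.radius_max_px} exceeds half the smaller "
            f"image dimension ({min(h, w) / 2})"
        )
    if not fg.any():
        return []

    r_lo = int(np.ceil(config.radius_min_px))
    r_hi = int(np.floor(config.radius_max_px))
    if r_hi < r_lo:
        return []

    # candidate centers: foreground pixels around medial-axis peaks
    dist = ndimage.distance_transform_edt(fg)
    min_dist = max(3, r_lo // 2)
    peaks = peak_local_max(
        dist, min_distance=min_dist, threshold_abs=1.0, exclude_border=False
    )
    if len(peaks) == 0:
        return []

    k = 3  # half-width of the refinement window around each peak
    margin = r_hi + 1
    seen: set[tuple[int, int]] = set()
    raw: list[AggregateDetection] = []
    for pr, pc in peaks:
        rs = slice(max(0, pr - margin - k), min(h, pr + margin + k + 1))
        cs = slice(max(0, pc - margin - k), min(w, pc + margin + k + 1))
        sub = fg[rs, cs]
        fr, fc = np.nonzero(sub)
        fr = fr + rs.start
        fc = fc + cs.start
        cand = []
        for rr in range(max(0, pr - k), min(h, pr + k + 1)):
            for cc in range(max(0, pc - k), min(w, pc + k + 1)):
                if fg[rr, cc] and (rr, cc) not in seen:
                    seen.add((rr, cc))
                    cand.append((rr, cc))
        if not cand:
            continue
        centers = np.asarray(cand, dtype=np.int64)
        votes = _vote_profiles(fr, fc, centers, r_lo, r_hi)
        for (rr, cc), profile in zip(cand, votes):
            sel = _select_radius(profile, r_lo, config.sensitivity, accept_frac)
            if sel is not None:
                radius, v = sel
                raw.append(
                    AggregateDetection(
                        center=(int(rr), int(cc)),
                        radius_px=float(radius),
                        votes=v,
                        pass_index=pass_index,
                    )
                )

    return sorted(dedupe_detections(raw), key=_detection_order)


def multi_pass_segment(
    image: np.ndarray,
    passes: tuple[HoughPassConfig, ...] | list[HoughPassConfig] = DEFAULT_PASSES,
    threshold: float = DEFAULT_THRESHOLD,
    accept_frac: float = 0.5,
) -> list[AggregateDetection]:
    """Binarize, run every Hough pass, stack and discard repeats.

    With the default schedule this is the five-pass procedure: radius
    ranges 20-200 through 90-200 px with sensitivities 0.72 through 0.92,
    the per-pass detections stacked and deduplicated into one fully
    segmented image.
    """
    passes = tuple(passes)
    if not passes:
        raise ConfigurationError("at least one Hough pass is required")
    binary = binarize(image, threshold)
    stacked: list[AggregateDetection] = []
    for i, cfg in enumerate(passes):
        stacked.extend(
            hough_detect(binary, cfg, accept_frac=accept_frac, pass_index=i)
        )
    return sorted(dedupe_detections(stacked), key=_detection_order)
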