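"""Side-view synapse profiling: the core trans-synaptic measurement.

A side-view synapse is one imaged edge-on, so the postsynaptic scaffold
(PSD-95 or Gephyrin, STED) appears as a single bar at the edge of the
presynaptic vesicle cloud (Synaptophysin, confocal).  For each such
synapse a 1 µm long, 250 nm wide intensity profile is taken perpendicular
to the scaffold bar through its center.  After a 5-pixel rolling average,
the scaffold peak is located; the protein-of-interest peak is the profile
maximum within 100 nm of the scaffold peak, and the signed peak-to-peak
distance (positive toward the presynapse) is the localization readout.
Profiles are aligned to the scaffold peak and averaged, and synapses are
called positive for the protein when their peak intensity exceeds the
knockout-reference mean by more than three standard deviations, assessed
per culture.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label, regionprops

from .segmentation import auto_threshold

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SideViewROI:
    """Geometry of one side-view profile: where and in which direction to sample."""

    bar_center: tuple[float, float]  # (x, y) nm
    axis_normal: tuple[float, float]  # unit vector, + toward the presynapse
    profile_length: float = 1000.0  # nm
    profile_width: float = 250.0  # nm
    source: str = "auto"  # "manual" | "auto"

    def __post_init__(self):
        n = math.hypot(*self.axis_normal)
        if n == 0:
            raise ValueError("axis_normal must be nonzero")
        if not math.isclose(n, 1.0, abs_tol=1e-6):
            object.__setattr__(self, "axis_normal", (self.axis_normal[0] / n, self.axis_normal[1] / n))
        if self.profile_length <= 0 or self.profile_width <= 0:
            raise ValueError("profile_length and profile_width must be > 0")


@dataclass
class LineProfile:
    """Width-averaged intensity vs position along the trans-synaptic axis."""

    positions: np.ndarray  # nm; 0 at bar_center (or scaffold peak after alignment)
    intensities: dict[str, np.ndarray]  # channel name -> counts
    smoothing_window: int = 0  # pixels; 0 = unsmoothed

    def __post_init__(self):
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        for name, v in self.intensities.items():
            if len(v) != len(self.positions):
                raise ValueError(f"channel {name!r} length mismatch")


@dataclass
class SideViewMeasurement:
    """Peak positions and the signed peak-to-peak distance of one synapse."""

    scaffold_peak_pos: float  # nm, in ROI coordinates (0 = bar_center)
    protein_peak_pos: float  # nm
    protein_peak_intensity: float  # counts
    distance: float  # nm, signed: protein - scaffold along +axis_normal
    window_truncated: bool
    positive: bool | None = None  # None = undetermined
    culture: str | None = None
    genotype: str | None = None


@dataclass
class AverageProfile:
    """Peak-aligned mean +/- SEM intensity vs position, per channel."""

    positions: np.ndarray  # nm relative to the scaffold peak
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_synapses: int


@dataclass(frozen=True)
class DetectionParams:
    """Criteria for automatic side-view candidate selection."""

    elongation_min: float = 2.0  # major/minor axis ratio of the scaffold bar
    adjacency_max: float = 200.0  # nm from bar centroid to a cloud boundary
    bar_length_min: float = 200.0  # nm
    bar_length_max: float = 800.0  # nm
    threshold_method: str = "otsu"
    profile_length: float = 1000.0
    profile_width: float = 250.0


def detect_sideview_candidates(
    scaffold: np.ndarray,
    vesicle: np.ndarray,
    pixel_size: float,
    params: DetectionParams = DetectionParams(),
) -> list[SideViewROI]:
    """Find bar-like scaffold structures at the edge of a single vesicle cloud.

    Scaffold components are kept when they are elongated (aspect ratio >=
    ``elongation_min``), of bar-like length, adjacent to exactly one vesicle
    cluster (centroid within ``adjacency_max`` of the cluster boundary) and
    not overlapping another bar.  The bar orientation comes from the
    component's second moments; the profile normal is signed toward the
    nearest cluster centroid, i.e. toward the presynapse.
    """
    if scaffold.shape != vesicle.shape:
        raise ValueError("scaffold and vesicle channels must share geometry")
    ves_mask = auto_threshold(vesicle, params.threshold_method)
    ves_lab = label(ves_mask, connectivity=2)
    clusters = regionprops(ves_lab)
    if not clusters:
        return []
    # distance (px) from any pixel to the nearest vesicle-cluster pixel
    dist_to_cloud = ndimage.distance_transform_edt(~ves_mask)

    bar_mask = auto_threshold(scaffold, params.threshold_method)
    bar_lab = label(bar_mask, connectivity=2)
    bars = regionprops(bar_lab)
    adjacency_px = params.adjacency_max / pixel_size

    rois: list[SideViewROI] = []
    for rp in bars:
        minor = rp.axis_minor_length
        if minor == 0 or rp.axis_major_length / minor < params.elongation_min:
            continue
        bar_len_nm = rp.axis_major_length * pixel_size
        if not (params.bar_length_min <= bar_len_nm <= params.bar_length_max):
            continue
        cy, cx = rp.centroid
        if dist_to_cloud[int(round(cy)), int(round(cx))] > adjacency_px:
            continue
        # a single adjacent cluster: count clusters whose pixels come within
        # adjacency_max of the bar's own pixels
        bar_px = rp.coords  # (row, col)
        near = np.zeros(ves_lab.max() + 1, dtype=bool)
        r0, c0 = bar_px[:, 0], bar_px[:, 1]
        pad = max(1, int(np.ceil(adjacency_px)))
        rmin, rmax = max(r0.min() - pad, 0), min(r0.max() + pad + 1, ves_lab.shape[0])
        cmin, cmax = max(c0.min() - pad, 0), min(c0.max() + pad + 1, ves_lab.shape[1])
        sub = np.zeros_like(bar_mask)
        sub[r0, c0] = True
        grown = ndimage.binary_dilation(
            sub[rmin:rmax, cmin:cmax], iterations=pad
        )
        near_ids = np.unique(ves_lab[rmin:rmax, cmin:cmax][grown])
        near_ids = near_ids[near_ids > 0]
        if len(near_ids) != 1:
            continue
        # reject bars touching another bar's dilated footprint ("single bar")
        other = np.unique(bar_lab[rmin:rmax, cmin:cmax][grown])
        if len(other[(other > 0) & (other != rp.label)]) > 0:
            continue
        cluster = clusters[int(near_ids[0]) - 1]
        ccy, ccx = cluster.centroid
        # orientation: angle of the major axis (skimage convention:
        # angle between the row axis and the major axis, CCW)
        theta = rp.orientation
        u = (math.sin(theta), math.cos(theta))  # (x, y) unit vector of long axis
        nvec = (-u[1], u[0])
        to_cloud = (ccx - cx, ccy - cy)
        if nvec[0] * to_cloud[0] + nvec[1] * to_cloud[1] < 0:
            nvec = (-nvec[0], -nvec[1])
        rois.append(
            SideViewROI(
                bar_center=(cx * pixel_size, cy * pixel_size),
                axis_normal=nvec,
                profile_length=params.profile_length,
                profile_width=params.profile_width,
                source="auto",
            )
        )
    return rois


def extract_profile(
    images: dict[str, np.ndarray],
    roi: SideViewROI,
    pixel_size: float,
) -> LineProfile:
    """Sample a width-averaged perpendicular profile through the bar center.

    Positions run from -length/2 to +length/2 in steps of one pixel, with 0
    at ``bar_center`` and + toward the presynapse; intensities at each
    position are the mean over ``profile_width`` sampled perpendicular to
    the profile axis (i.e. along the bar), using bilinear interpolation.
    """
    if not images:
        raise ValueError("no channels to sample")
    shape = next(iter(images.values())).shape
    nx, ny = roi.axis_normal
    ux, uy = ny, -nx  # bar long-axis direction (either sign; averaged over)

    half_l = roi.profile_length / 2.0
    n_steps = int(math.floor(half_l / pixel_size))
    s = np.arange(-n_steps, n_steps + 1) * pixel_size  # nm along the normal
    half_w = roi.profile_width / 2.0
    n_w = int(math.floor(half_w / pixel_size))
    w = np.arange(-n_w, n_w + 1) * pixel_size  # nm along the bar axis

    cx, cy = roi.bar_center
    # sample grid in nm: S x W
    Xs = cx + s[:, None] * nx + w[None, :] * ux
    Ys = cy + s[:, None] * ny + w[None, :] * uy
    rows = Ys / pixel_size
    cols = Xs / pixel_size
    if (rows.min() < -1e-9 or cols.min() < -1e-9
            or rows.max() > shape[0] - 1 + 1e-9 or cols.max() > shape[1] - 1 + 1e-9):
        raise ValueError(
            f"ROI at ({cx:.0f}, {cy:.0f}) nm exceeds image bounds "
            f"({roi.profile_length:.0f} x {roi.profile_width:.0f} nm profile)"
        )
    intensities = {}
    for name, img in images.items():
        vals = ndimage.map_coordinates(
            np.asarray(img, dtype=float), [rows, cols], order=1, mode="nearest"
        )
        intensities[name] = vals.mean(axis=1)
    return LineProfile(positions=s.astype(float), intensities=intensities, smoothing_window=0)


def smooth_profile(p: LineProfile, k: int = 5) -> LineProfile:
    """Centered k-pixel rolling average; edges use shrinking windows."""
    if k < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(k)
    counts = np.convolve(np.ones(len(p.positions)), kernel, mode="same")
    smoothed = {
        name: np.convolve(v, kernel, mode="same") / counts for name, v in p.intensities.items()
    }
    return LineProfile(positions=p.positions.copy(), intensities=smoothed, smoothing_window=k)


def _peak_index(values: np.ndarray, positions: np.ndarray) -> int:
    """Index of the maximum; ties broken toward position 0 (and logged)."""
    m = values.max()
    idx = np.flatnonzero(values == m)
    if len(idx) > 1:
        log.warning("tied maxima at positions %s; choosing nearest 0", positions[idx])
    return int(idx[np.argmin(np.abs(positions[idx]))])


def measure_apposition(
    p: LineProfile,
    scaffold_channel: str,
    protein_channel: str,
    window_nm: float = 100.0,
) -> SideViewMeasurement:
    """Signed peak-to-peak distance between protein and scaffold peaks.

    The scaffold peak is the global maximum of the (smoothed) scaffold
    profile; the protein peak is the maximum within ``window_nm`` of it
    (inclusive).  ``window_truncated`` is set when the protein maximum sits
    at a window edge, i.e. the true peak may lie outside the search window.
    """
    if p.smoothing_window < 1:
        warnings.warn("measure_apposition called on an unsmoothed profile", stacklevel=2)
    pos = p.positions
    i_scaf = _peak_index(p.intensities[scaffold_channel], pos)
    scaffold_pos = pos[i_scaf]
    in_win = np.abs(pos - scaffold_pos) <= window_nm + 1e-9
    win_idx = np.flatnonzero(in_win)
    prot = p.intensities[protein_channel][win_idx]
    j = win_idx[_peak_index(prot, pos[win_idx] - scaffold_pos)]
    protein_pos = pos[j]
    # a maximum sitting on either window edge means the true peak may lie
    # beyond the search window
    truncated = j == win_idx[0] or j == win_idx[-1]
    return SideViewMeasurement(
        scaffold_peak_pos=float(scaffold_pos),
        protein_peak_pos=float(protein_pos),
        protein_peak_intensity=float(p.intensities[protein_channel][j]),
        distance=float(protein_pos - scaffold_pos),
        window_truncated=bool(truncated),
    )


def align_and_average(
    measurements: Sequence[SideViewMeasurement],
    profiles: Sequence[LineProfile],
) -> AverageProfile:
    """Shift each profile so its scaffold peak is at 0, resample, average.

    Profiles are resampled by linear interpolation onto a common grid (one
    pixel step, restricted to positions covered by every shifted profile).
    SEM is the sample SD divided by sqrt(n); with fewer than 2 profiles the
    SEM is returned as NaN.
    """
    if len(measurements) != len(profiles):
        raise ValueError("need one measurement per profile")
    if not profiles:
        raise ValueError("no profiles to average")
    step = float(np.diff(profiles[0].positions).mean())
    lo = max(p.positions[0] - m.scaffold_peak_pos for p, m in zip(profiles, measurements))
    hi = min(p.positions[-1] - m.scaffold_peak_pos for p, m in zip(profiles, measurements))
    n_lo = int(np.ceil(lo / step - 1e-9))
    n_hi = int(np.floor(hi / step + 1e-9))
    grid = np.arange(n_lo, n_hi + 1) * step

    channels = list(profiles[0].intensities)
    mean: dict[str, np.ndarray] = {}
    sem: dict[str, np.ndarray] = {}
    for ch in channels:
        stack = np.vstack(
            [
                np.interp(grid, p.positions - m.scaffold_peak_pos, p.intensities[ch])
                for p, m in zip(profiles, measurements)
            ]
        )
        mean[ch] = stack.mean(axis=0)
        if len(profiles) >= 2:
            sem[ch] = stack.std(axis=0, ddof=1) / math.sqrt(len(profiles))
        else:
            sem[ch] = np.full(grid.shape, np.nan)
    return AverageProfile(positions=grid, mean=mean, sem=sem, n_synapses=len(profiles))


def classify_positive(
    peak_intensities: Sequence[float],
    cultures: Sequence[str],
    ko_reference: dict[str, Sequence[float]],
    n_sd: float = 3.0,
) -> pd.DataFrame:
    """Knockout-referenced positivity call, per culture.

    For each culture g the threshold is mean(KO_g) + ``n_sd`` * SD(KO_g)
    (sample SD, n-1 denominator); a synapse is positive iff its peak
    intensity is strictly greater than the threshold of its own culture.
    Cultures with fewer than 2 KO reference values yield undetermined
    calls.  Returns a DataFrame with columns ``peak``, ``culture``,
    ``threshold``, ``positive`` (nullable boolean).
    """
    thresholds: dict[str, float] = {}
    for g, vals in ko_reference.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            warnings.warn(f"culture {g!r} has < 2 KO reference values; calls undetermined", stacklevel=2)
            thresholds[g] = float("nan")
        else:
            thresholds[g] = float(vals.mean() + n_sd * vals.std(ddof=1))
    rows = []
    for peak, g in zip(peak_intensities, cultures):
        thr = thresholds.get(g, float("nan"))
        call = None if math.isnan(thr) else bool(peak > thr)
        rows.append({"peak": float(peak), "culture": g, "threshold": thr, "positive": call})
    df = pd.DataFrame(rows)
    df["positive"] = df["positive"].astype("boolean")
    return df


def positive_fraction(calls: pd.DataFrame) -> dict[str, float]:
    """Pooled and per-culture positive fractions over determined calls."""
    det = calls.dropna(subset=["positive"])
    out = {"pooled": float(det["positive"].mean()) if len(det) else float("nan")}
    for g, grp in det.groupby("culture"):
        out[str(g)] = float(grp["positive"].mean())
    return out
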