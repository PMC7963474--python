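"""Ground-truthed synthetic scenes and current traces.

Emulates the experimental inputs of two-color STED / confocal imaging of
cultured neurons: a confocal vesicle-cloud channel (Synaptophysin-like
blobs), a STED postsynaptic-scaffold channel (PSD-95 / Gephyrin-like bars
at the edge of the cloud), and a STED protein-of-interest channel rendered
as a parallel band displaced across the cleft by a known signed offset.
Each channel is blurred with its own Gaussian PSF and corrupted by
Poisson + Gaussian detector noise.  Knockout-genotype scenes set the
protein amplitude to zero so that only background remains.

Also generates whole-cell evoked-current traces as baseline-shifted
double exponentials, the standard phenomenological IPSC waveform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: roll-off length (nm) of the soft top-hat ends of scaffold bars and of
#: the vesicle-cloud disk edge
EDGE_SOFTNESS_NM = 20.0

_ROLES = ("vesicle", "scaffold", "protein")


@dataclass(frozen=True)
class ChannelSpec:
    """One acquisition channel: marker, modality, PSF and detector model."""

    marker_name: str
    modality: str = "sted"  # "confocal" | "sted"
    psf_fwhm: float = 50.0  # nm
    background: float = 2.0  # mean counts per pixel
    gain: float = 1.0  # counts per photon
    role: str = ""  # "vesicle" | "scaffold" | "protein"; inferred if empty

    def __post_init__(self):
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.modality not in ("confocal", "sted"):
            raise ValueError(f"unknown modality {self.modality!r}")
        role = self.role or _infer_role(self.marker_name)
        if role not in _ROLES:
            raise ValueError(f"channel role must be one of {_ROLES}, got {role!r}")
        object.__setattr__(self, "role", role)


def _infer_role(marker: str) -> str:
    m = marker.lower()
    if "synaptophysin" in m or "vesicle" in m:
        return "vesicle"
    if m in ("psd-95", "psd95", "gephyrin") or "scaffold" in m:
        return "scaffold"
    return "protein"


@dataclass(frozen=True)
class SynapseGroundTruth:
    """True geometry and photometry of one simulated side-view synapse.

    ``orientation`` is the unit vector of the scaffold bar's long axis;
    ``cloud_side`` gives the sign of the presynaptic side along the axis
    normal (the 90deg counter-clockwise rotation of ``orientation``);
    ``true_offset`` displaces the protein band from the scaffold bar along
    that normal, positive values pointing toward the presynaptic cloud.
    """

    center: tuple[float, float]  # (x, y) nm
    orientation: tuple[float, float] = (1.0, 0.0)
    bar_length: float = 400.0  # nm
    bar_thickness_sigma: float = 30.0  # nm (Gaussian cross-section)
    cloud_radius: float = 400.0  # nm (bouton-sized: ~0.5 um^2 cross-section)
    cloud_side: int = 1  # +1 | -1
    true_offset: float = 0.0  # nm, + toward presynapse
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"vesicle": 800.0, "scaffold": 1000.0, "protein": 1000.0}
    )

    def __post_init__(self):
        n = math.hypot(*self.orientation)
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-6):
            if n == 0:
                raise ValueError("orientation must be a nonzero vector")
            object.__setattr__(self, "orientation", (self.orientation[0] / n, self.orientation[1] / n))
        if self.cloud_side not in (1, -1):
            raise ValueError("cloud_side must be +1 or -1")
        if self.bar_length <= 0:
            raise ValueError("bar_length must be > 0")

    @property
    def axis_normal(self) -> tuple[float, float]:
        """Unit normal of the bar, signed toward the presynaptic cloud."""
        ux, uy = self.orientation
        return (-uy * self.cloud_side, ux * self.cloud_side)

    @property
    def cloud_center(self) -> tuple[float, float]:
        nx, ny = self.axis_normal
        return (self.center[0] + nx * self.cloud_radius, self.center[1] + ny * self.cloud_radius)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic multi-channel field of view."""

    image_size: tuple[int, int] = (256, 256)  # (H, W) pixels
    pixel_size: float = 20.0  # nm / pixel
    channels: Sequence[ChannelSpec] = ()
    synapses: Sequence[SynapseGroundTruth] = ()
    distractors: int = 0
    noise: str = "none"  # "none" | "poisson" | "poisson+gaussian"
    read_sigma: float = 1.0  # counts, Gaussian read noise
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if len(self.channels) == 0:
            raise ValueError("SceneSpec needs at least one channel")


@dataclass
class SyntheticScene:
    """Rendered rasters plus the ground-truth table used to make them."""

    spec: SceneSpec
    images: dict[str, np.ndarray]  # marker_name -> (H, W) float counts
    truth: "pd.DataFrame"
    dropped: list[int]  # indices of synapses rejected as out of bounds

    def channel(self, role: str) -> np.ndarray:
        """Return the raster of the (unique) channel with the given role."""
        names = [c.marker_name for c in self.spec.channels if c.role == role]
        if len(names) != 1:
            raise KeyError(f"expected exactly one {role!r} channel, found {len(names)}")
        return self.images[names[0]]


def default_channels(
    sted_fwhm: float = 50.0, confocal_fwhm: float = 250.0, background: float = 2.0
) -> list[ChannelSpec]:
    """The canonical three-channel layout used throughout the tests."""
    return [
        ChannelSpec("Synaptophysin", "confocal", confocal_fwhm, background, role="vesicle"),
        ChannelSpec("scaffold", "sted", sted_fwhm, background, role="scaffold"),
        ChannelSpec("protein", "sted", sted_fwhm, background, role="protein"),
    ]


def _soft_tophat(d: np.ndarray, half_width: float, edge: float = EDGE_SOFTNESS_NM) -> np.ndarray:
    return 0.5 * (1.0 + erf((half_width - np.abs(d)) / (math.sqrt(2.0) * edge)))


def _bar_field(X, Y, center, orientation, normal, length, sigma, shift_nm=0.0):
    """Gaussian cross-section along the normal, soft top-hat along the axis."""
    cx = center[0] + normal[0] * shift_nm
    cy = center[1] + normal[1] * shift_nm
    dx, dy = X - cx, Y - cy
    d_along = dx * orientation[0] + dy * orientation[1]
    d_perp = dx * normal[0] + dy * normal[1]
    return np.exp(-0.5 * (d_perp / sigma) ** 2) * _soft_tophat(d_along, length / 2.0)


def _disk_field(X, Y, center, radius):
    r = np.hypot(X - center[0], Y - center[1])
    return 0.5 * (1.0 + erf((radius - r) / (math.sqrt(2.0) * EDGE_SOFTNESS_NM)))


def _in_bounds(s: SynapseGroundTruth, extent_x: float, extent_y: float) -> bool:
    ux, uy = s.orientation
    nx, ny = s.axis_normal
    half = s.bar_length / 2.0 + 3.0 * s.bar_thickness_sigma
    pts = [
        (s.center[0] + ux * half, s.center[1] + uy * half),
        (s.center[0] - ux * half, s.center[1] - uy * half),
        (s.center[0] + nx * (s.true_offset + 3 * s.bar_thickness_sigma),
         s.center[1] + ny * (s.true_offset + 3 * s.bar_thickness_sigma)),
        (s.cloud_center[0] + 1.2 * s.cloud_radius * nx, s.cloud_center[1] + 1.2 * s.cloud_radius * ny),
        (s.cloud_center[0] - 1.2 * s.cloud_radius * nx, s.cloud_center[1] - 1.2 * s.cloud_radius * ny),
    ]
    return all(0.0 <= x <= extent_x and 0.0 <= y <= extent_y for x, y in pts)


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a multi-channel raster scene with per-synapse ground truth.

    The scaffold channel shows each synapse as a Gaussian-profile bar, the
    protein channel as a parallel band displaced by ``true_offset`` toward
    the presynapse, and the vesicle channel as a soft disk on the
    presynaptic side.  Each channel is convolved with a normalized Gaussian
    PSF of its own FWHM; noise is applied last.  Synapses whose footprint
    falls outside the image are dropped and reported in ``dropped``.
    Output coordinates are nm with the origin at the top-left pixel center.
    """
    import pandas as pd

    H, W = spec.image_size
    px = spec.pixel_size
    extent_x, extent_y = (W - 1) * px, (H - 1) * px
    xs = np.arange(W) * px
    ys = np.arange(H) * px
    X, Y = np.meshgrid(xs, ys)

    rng = np.random.default_rng(spec.seed)

    kept: list[SynapseGroundTruth] = []
    dropped: list[int] = []
    for i, s in enumerate(spec.synapses):
        if _in_bounds(s, extent_x, extent_y):
            kept.append(s)
        else:
            dropped.append(i)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} out-of-bounds synapse(s): {dropped}", stacklevel=2)

    fields = {role: np.zeros((H, W)) for role in _ROLES}
    for s in kept:
        amp = {r: float(s.amplitudes.get(r, 0.0)) for r in _ROLES}
        normal = s.axis_normal
        if amp["scaffold"]:
            fields["scaffold"] += amp["scaffold"] * _bar_field(
                X, Y, s.center, s.orientation, normal, s.bar_length, s.bar_thickness_sigma
            )
        if amp["protein"]:
            fields["protein"] += amp["protein"] * _bar_field(
                X, Y, s.center, s.orientation, normal, s.bar_length, s.bar_thickness_sigma,
                shift_nm=s.true_offset,
            )
        if amp["vesicle"]:
            fields["vesicle"] += amp["vesicle"] * _disk_field(X, Y, s.cloud_center, s.cloud_radius)

    for _ in range(spec.distractors):
        # round non-synaptic blobs in every channel, placed uniformly
        cx, cy = rng.uniform(0, extent_x), rng.uniform(0, extent_y)
        sigma = rng.uniform(60.0, 120.0)
        amp = rng.uniform(100.0, 400.0)
        blob = amp * np.exp(-0.5 * ((X - cx) ** 2 + (Y - cy) ** 2) / sigma**2)
        fields[rng.choice(_ROLES)] += blob

    images: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        sigma_px = ch.psf_fwhm * FWHM_TO_SIGMA / px
        photons = gaussian_filter(fields[ch.role], sigma_px, mode="constant")
        lam = photons + ch.background / max(ch.gain, 1e-300)
        if spec.noise == "none":
            counts = ch.gain * lam
        else:
            counts = ch.gain * rng.poisson(lam).astype(float)
            if spec.noise == "poisson+gaussian":
                counts = counts + rng.normal(0.0, spec.read_sigma, size=counts.shape)
        images[ch.marker_name] = counts

    rows = []
    for s in kept:
        rows.append(
            {
                "center_x_nm": s.center[0],
                "center_y_nm": s.center[1],
                "orientation_x": s.orientation[0],
                "orientation_y": s.orientation[1],
                "bar_length_nm": s.bar_length,
                "bar_thickness_sigma_nm": s.bar_thickness_sigma,
                "cloud_radius_nm": s.cloud_radius,
                "cloud_side": s.cloud_side,
                "true_offset_nm": s.true_offset,
                **{f"amplitude_{r}": float(s.amplitudes.get(r, 0.0)) for r in _ROLES},
            }
        )
    truth = pd.DataFrame(rows)
    return SyntheticScene(spec=spec, images=images, truth=truth, dropped=dropped)


def grid_scene_spec(
    true_offsets: Sequence[float],
    seed: int = 0,
    pixel_size: float = 20.0,
    sted_fwhm: float = 50.0,
    confocal_fwhm: float = 250.0,
    noise: str = "poisson+gaussian",
    read_sigma: float = 1.0,
    background: float = 2.0,
    protein_amplitude: float = 1000.0,
    scaffold_amplitude: float = 1000.0,
    vesicle_amplitude: float = 800.0,
    cell_nm: float = 2200.0,
    distractors: int = 0,
) -> SceneSpec:
    """Build a scene with one synapse per grid cell, random orientations.

    One synapse is placed per ``cell_nm`` x ``cell_nm`` cell (with jitter),
    with uniformly random bar orientation and presynaptic side, and the
    given per-synapse protein offsets.  Knockout-genotype scenes are made
    by setting ``protein_amplitude`` to 0.  This is the workhorse used by
    the pipeline and the validation experiments.
    """
    rng = np.random.default_rng(seed)
    n = len(true_offsets)
    cols = int(math.ceil(math.sqrt(n)))
    rows_n = int(math.ceil(n / cols))
    side_px = int(round(cell_nm / pixel_size))
    H, W = rows_n * side_px, cols * side_px
    synapses = []
    for i, off in enumerate(true_offsets):
        r, c = divmod(i, cols)
        cx = (c + 0.5) * cell_nm + rng.uniform(-100, 100)
        cy = (r + 0.5) * cell_nm + rng.uniform(-100, 100)
        theta = rng.uniform(0, math.pi)
        synapses.append(
            SynapseGroundTruth(
                center=(cx, cy),
                orientation=(math.cos(theta), math.sin(theta)),
                cloud_side=int(rng.choice([1, -1])),
                true_offset=float(off),
                amplitudes={
                    "vesicle": vesicle_amplitude,
                    "scaffold": scaffold_amplitude,
                    "protein": protein_amplitude,
                },
            )
        )
    return SceneSpec(
        image_size=(H, W),
        pixel_size=pixel_size,
        channels=default_channels(sted_fwhm, confocal_fwhm, background),
        synapses=synapses,
        distractors=distractors,
        noise=noise,
        read_sigma=read_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# --------------------------------------------------------------------------
# Evoked-current traces


@dataclass(frozen=True)
class IPSCParams:
    """Parameters of a synthetic evoked-IPSC trace (double exponential)."""

    amplitude: float = 1000.0  # pA, peak magnitude of each unscaled response
    tau_rise: float = 1.0  # ms
    tau_decay: float = 10.0  # ms
    onset_latency: float = 3.0  # ms after the stimulus (past the artifact blank)
    baseline: float = 0.0  # pA holding current
    noise_sigma: float = 0.0  # pA additive Gaussian noise
    stimulus_times: tuple[float, ...] = (50.0,)  # ms
    ppr_true: float = 1.0  # scales the second (and later) responses
    duration: float = 300.0  # ms record length
    dt: float = 0.1  # ms sampling interval (10 kHz)

    def __post_init__(self):
        if self.tau_decay <= self.tau_rise or self.tau_rise <= 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def ipsc_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time-to-peak of the unit double exponential (after onset)."""
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def double_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalizer so the double exponential's extremum magnitude is 1."""
    t_star = ipsc_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise))


def ipsc_waveform(t: np.ndarray, t0: float, amplitude: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Inward (negative-going) IPSC component starting at ``t0``, peak ``-amplitude``."""
    dt = np.clip(t - t0, 0.0, None)
    w = np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise)
    return -amplitude * double_exp_norm(tau_rise, tau_decay) * np.where(t >= t0, w, 0.0)


def generate_trace(params: IPSCParams, seed: int | None = None):
    """Simulate a whole-cell current record with evoked double-exponential IPSCs.

    current(t) = baseline + sum_i scale_i * waveform(t - stim_i - latency),
    where scale_i is 1 for the first stimulus and ``ppr_true`` afterwards,
    plus additive Gaussian noise.  Returns an :class:`stedview.ephys.Trace`.
    """
    from .ephys import Trace

    t = np.arange(0.0, params.duration, params.dt)
    current = np.full_like(t, params.baseline)
    for i, ts in enumerate(params.stimulus_times):
        scale = 1.0 if i == 0 else params.ppr_true
        if params.amplitude > 0:
            current += scale * ipsc_waveform(
                t, ts + params.onset_latency, params.amplitude, params.tau_rise, params.tau_decay
            )
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, params.noise_sigma, size=t.shape)
    return Trace(time=t, current=current, stimulus_times=tuple(params.stimulus_times))
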