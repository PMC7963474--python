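"""Ground-truth recovery experiments for end-to-end validation.

Because the kind of raw STED/electrophysiology data this pipeline targets
is rarely shareable, validation is property-based: scenes and traces with
known ground truth are generated, pushed through the full measurement
chain (automatic side-view detection -> profile extraction -> smoothing ->
apposition measurement; trace -> kinetics/PPR), and the recovered values
are compared against the generator's truth or against independent
closed-form oracles.  Every experiment here is driven by a single seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .profiling import (
    SideViewROI,
    classify_positive,
    detect_sideview_candidates,
    extract_profile,
    measure_apposition,
    positive_fraction,
    smooth_profile,
)
from .segmentation import detect_puncta
from .synthetic import (
    IPSCParams,
    double_exp_norm,
    generate_trace,
    grid_scene_spec,
    ipsc_peak_time,
    render_scene,
)
from .ephys import measure_ipsc, paired_pulse_ratio


def measure_synapse(true_offset: float, seed: int, pixel_size: float = 20.0,
                    sted_fwhm: float = 50.0, noise: str = "poisson+gaussian"):
    """Render one synapse and run the fully automatic measurement chain.

    Returns the signed measured distance in nm, or NaN when the automatic
    detector finds no (or more than one) side-view candidate.
    """
    spec = grid_scene_spec([true_offset], seed=seed, pixel_size=pixel_size,
                           sted_fwhm=sted_fwhm, noise=noise)
    scene = render_scene(spec)
    rois = detect_sideview_candidates(
        scene.channel("scaffold"), scene.channel("vesicle"), pixel_size
    )
    if len(rois) != 1:
        return float("nan")
    p = smooth_profile(extract_profile(scene.images, rois[0], pixel_size), 5)
    return measure_apposition(p, "scaffold", "protein").distance


def offset_recovery(offsets=(0.0, 20.0, 40.0, 60.0, 80.0), n_per_offset: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Mean absolute distance error per true offset over many synapses."""
    rng = np.random.default_rng(seed)
    rows = []
    for off in offsets:
        errs, misses = [], 0
        for _ in range(n_per_offset):
            d = measure_synapse(off, int(rng.integers(0, 2**31 - 1)))
            if math.isnan(d):
                misses += 1
            else:
                errs.append(abs(d - off))
        rows.append(
            {
                "true_offset_nm": off,
                "n_measured": len(errs),
                "n_missed": misses,
                "mae_nm": float(np.mean(errs)) if errs else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def distribution_recovery(n: int = 50, mean_nm: float = 24.0, sd_nm: float = 17.0,
                          seed: int = 0) -> dict:
    """Recover the offset distribution of a population of synapses.

    Offsets are drawn from N(mean, sd^2); the pipeline's unsigned distance
    distribution is compared against the drawn truth.
    """
    rng = np.random.default_rng(seed)
    true = rng.normal(mean_nm, sd_nm, n)
    measured = []
    for off in true:
        d = measure_synapse(float(off), int(rng.integers(0, 2**31 - 1)))
        if not math.isnan(d):
            measured.append(d)
    measured = np.asarray(measured)
    return {
        "n": len(measured),
        "true_mean_unsigned_nm": float(np.abs(true).mean()),
        "true_sd_unsigned_nm": float(np.abs(true).std(ddof=1)),
        "measured_mean_unsigned_nm": float(np.abs(measured).mean()),
        "measured_sd_unsigned_nm": float(np.abs(measured).std(ddof=1)),
    }


def null_positivity_rate(n: int = 100_000, seed: int = 0) -> dict:
    """False-positive rate of the 3-SD positivity rule under a Gaussian null.

    Test peaks are drawn from the same Gaussian as the knockout reference,
    so the expected positive fraction is the standard-normal upper tail
    P(Z > 3) = 0.135%.
    """
    rng = np.random.default_rng(seed)
    ko = rng.normal(100.0, 10.0, n)
    test = rng.normal(100.0, 10.0, n)
    calls = classify_positive(test, ["culture"] * n, {"culture": ko})
    return {"n": n, "positive_fraction": positive_fraction(calls)["pooled"]}


def size_filter_agreement(n_images: int = 20, seed: int = 0, pixel_size: float = 100.0) -> dict:
    """Compare retained puncta against brute-force pixel-count enumeration.

    Constructed label images contain well-separated rectangular components
    of known pixel area (including the exact filter bounds); agreement is
    the fraction of images whose retained-area multiset matches exactly.
    """
    rng = np.random.default_rng(seed)
    px_um2 = (pixel_size / 1000.0) ** 2
    agree = 0
    for _ in range(n_images):
        areas = list(rng.integers(1, 300, rng.integers(1, 9)))
        if rng.random() < 0.5:
            areas.append(int(round(0.4 / px_um2)))  # exactly the lower bound
            areas.append(int(round(2.0 / px_um2)))  # exactly the upper bound
        img = np.zeros((300, 400))
        x = 5
        for a in areas:
            w = int(np.ceil(np.sqrt(a)))
            h = int(np.ceil(a / w))
            block = np.zeros((h, w))
            block.flat[:a] = 100.0
            img[5 : 5 + h, x : x + w] = block
            x += w + 5
        table = detect_puncta(img, pixel_size=pixel_size)
        expected = sorted(a * px_um2 for a in areas if 0.4 <= a * px_um2 <= 2.0)
        got = sorted(table.puncta.area_um2)
        if len(got) == len(expected) and np.allclose(got, expected):
            agree += 1
    return {"n": n_images, "agreement_fraction": agree / n_images}


def rotation_oracle_errors(n_orientations: int = 20, seed: int = 0,
                           pixel_size: float = 20.0) -> dict:
    """Oblique profile sampling vs resampling the image on a rotated grid.

    The oracle resamples the whole raster onto a grid whose rows run along
    the signed profile normal (one bilinear affine transform), then reads
    axis-aligned rows; errors are reported as a fraction of the image max.
    """
    from .synthetic import ChannelSpec, SceneSpec, SynapseGroundTruth

    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_orientations):
        theta = float(rng.uniform(0, math.pi))
        center = (64 * pixel_size, 64 * pixel_size)
        syn = SynapseGroundTruth(
            center=center, orientation=(math.cos(theta), math.sin(theta)),
            amplitudes={"scaffold": 1000.0},
        )
        spec = SceneSpec(
            (129, 129), pixel_size,
            [ChannelSpec("scaffold", "sted", 50.0, 0.0, role="scaffold")],
            [syn], noise="none",
        )
        img = render_scene(spec).images["scaffold"]
        roi = SideViewROI(bar_center=center, axis_normal=syn.axis_normal)
        prof = extract_profile({"scaffold": img}, roi, pixel_size).intensities["scaffold"]
        nx, ny = roi.axis_normal
        A = np.array([[ny, -nx], [nx, ny]])
        c = 64
        c_in = np.array([center[1] / pixel_size, center[0] / pixel_size])
        c_out = np.array([float(c), float(c)])
        rot = ndimage.affine_transform(img, A, offset=c_in - A @ c_out, order=1, mode="nearest")
        nsteps = (len(prof) - 1) // 2
        nw = int(250 / 2 / pixel_size)
        oracle = rot[c - nsteps : c + nsteps + 1, c - nw : c + nw + 1].mean(axis=1)
        errs.append(float(np.max(np.abs(prof - oracle)) / img.max()))
    return {"n": n_orientations, "max_error_fraction_of_max": float(np.max(errs))}


def ipsc_kinetics_oracle_errors(
    tau_grid=((0.5, 5.0), (1.0, 10.0), (2.0, 20.0), (1.0, 5.0), (3.0, 30.0)),
    dt: float = 0.01,
) -> dict:
    """Rise/decay times vs bisection on the closed-form double exponential."""
    max_rise_err = max_decay_err = 0.0
    for tau_r, tau_d in tau_grid:
        tr = generate_trace(
            IPSCParams(amplitude=100.0, tau_rise=tau_r, tau_decay=tau_d,
                       noise_sigma=0.0, dt=dt,
                       duration=max(300.0, 60.0 + 10 * tau_d))
        )
        m = measure_ipsc(tr)
        norm = double_exp_norm(tau_r, tau_d)
        t_pk = ipsc_peak_time(tau_r, tau_d)

        def f(t):
            return norm * (math.exp(-t / tau_d) - math.exp(-t / tau_r))

        t20 = brentq(lambda t: f(t) - 0.2, 1e-12, t_pk, xtol=1e-12)
        t80 = brentq(lambda t: f(t) - 0.8, 1e-12, t_pk, xtol=1e-12)
        t33 = brentq(lambda t: f(t) - 0.33, t_pk, 200 * tau_d, xtol=1e-12)
        max_rise_err = max(max_rise_err, abs(m.rise_20_80 - (t80 - t20)))
        max_decay_err = max(max_decay_err, abs(m.decay_100_33 - (t33 - t_pk)))
    return {
        "n": len(tau_grid),
        "max_rise_error_ms": float(max_rise_err),
        "max_decay_error_ms": float(max_decay_err),
    }


def ppr_recovery_errors(intervals=(25.0, 50.0, 100.0, 200.0, 400.0),
                        ppr_true: float = 0.8, seed: int = 0) -> dict:
    """Paired-pulse ratio recovery with decay subtraction, high SNR."""
    errs = []
    for i, iv in enumerate(intervals):
        tr = generate_trace(
            IPSCParams(amplitude=1000.0, stimulus_times=(50.0, 50.0 + iv),
                       ppr_true=ppr_true, noise_sigma=5.0,
                       duration=50.0 + iv + 250.0),
            seed=seed + i,
        )
        r = paired_pulse_ratio(tr, subtract_decay=True)
        errs.append(abs(r - ppr_true) / ppr_true)
    return {"n": len(intervals), "max_relative_error": float(np.max(errs))}
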