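import math

import numpy as np
import pytest

from stedview.synthetic import (
    ChannelSpec,
    SceneSpec,
    SynapseGroundTruth,
    render_scene,
)


@pytest.fixture
def single_synapse_scene():
    """Factory: a one-synapse noise-free scene, centered, configurable."""

    def make(
        true_offset=0.0,
        theta=0.0,
        noise="none",
        seed=0,
        sted_fwhm=50.0,
        pixel_size=20.0,
        image_px=129,
        bar_thickness_sigma=30.0,
        background=0.0,
        cloud_side=1,
        protein_amplitude=1000.0,
    ):
        center = ((image_px - 1) / 2 * pixel_size,) * 2
        syn = SynapseGroundTruth(
            center=center,
            orientation=(math.cos(theta), math.sin(theta)),
            bar_thickness_sigma=bar_thickness_sigma,
            cloud_side=cloud_side,
            true_offset=true_offset,
            amplitudes={"vesicle": 800.0, "scaffold": 1000.0, "protein": protein_amplitude},
        )
        channels = [
            ChannelSpec("Synaptophysin", "confocal", 250.0, background, role="vesicle"),
            ChannelSpec("scaffold", "sted", sted_fwhm, background, role="scaffold"),
            ChannelSpec("protein", "sted", sted_fwhm, background, role="protein"),
        ]
        spec = SceneSpec(
            image_size=(image_px, image_px),
            pixel_size=pixel_size,
            channels=channels,
            synapses=[syn],
            noise=noise,
            seed=seed,
        )
        return render_scene(spec), syn

    return make


def two_way_anova_oracle(df):
    """Direct balanced two-way ANOVA decomposition (genotype x position).

    Independent of statsmodels: computes sums of squares from cell means on
    a balanced design with replicates, returning F statistics for the two
    main effects and the interaction.
    """
    y = df["intensity"].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = sorted(df["genotype"].unique())
    b_levels = sorted(df["position"].unique())
    a, b = len(a_levels), len(b_levels)
    n_cell = len(df) // (a * b)
    assert len(df) == a * b * n_cell, "oracle requires a balanced design"

    am = {g: df.loc[df["genotype"] == g, "intensity"].mean() for g in a_levels}
    bm = {q: df.loc[df["position"] == q, "intensity"].mean() for q in b_levels}
    cm = {
        (g, q): df.loc[(df["genotype"] == g) & (df["position"] == q), "intensity"].mean()
        for g in a_levels
        for q in b_levels
    }
    ss_a = b * n_cell * sum((am[g] - grand) ** 2 for g in a_levels)
    ss_b = a * n_cell * sum((bm[q] - grand) ** 2 for q in b_levels)
    ss_ab = n_cell * sum(
        (cm[g, q] - am[g] - bm[q] + grand) ** 2 for g in a_levels for q in b_levels
    )
    ss_resid = sum(
        (v - cm[g, q]) ** 2
        for g, q, v in zip(df["genotype"], df["position"], y)
    )
    df_a, df_b = a - 1, (b - 1)
    df_ab = df_a * df_b
    df_e = a * b * (n_cell - 1)
    ms_e = ss_resid / df_e
    return {
        "genotype": (ss_a / df_a) / ms_e,
        "position": (ss_b / df_b) / ms_e,
        "interaction": (ss_ab / df_ab) / ms_e,
    }
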