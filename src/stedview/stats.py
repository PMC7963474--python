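"""Assumption-gated group comparisons and profile-window ANOVA.

Two-sample comparisons use an unpaired two-sided t-test when both samples
pass Shapiro normality tests and Levene's homogeneity-of-variance test
(all p > alpha), and a two-sided Mann–Whitney U test otherwise.  Aligned
STED line profiles are compared across genotypes with a two-way ANOVA
(genotype x position, both categorical, interaction included) restricted
to a 200 nm window centered on the scaffold peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SIG_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for thr, s in SIG_STARS:
        if p < thr:
            return s
    return "ns"


@dataclass
class TwoSampleResult:
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    n1: int
    n2: int
    shapiro_p: tuple[float, float]
    levene_p: float


@dataclass
class ProfileAnovaResult:
    window_nm: float
    table: pd.DataFrame  # index: genotype, position, interaction; columns F, p, df
    n_per_genotype: dict[str, int]
    degenerate: bool = False


def choose_and_run_test(sample1, sample2, alpha: float = 0.05) -> TwoSampleResult:
    """Shapiro/Levene-gated choice between a t-test and Mann–Whitney U.

    All gating tests must exceed ``alpha`` for the parametric path.
    Constant samples make Shapiro undefined; they fail the gate and fall
    back to Mann–Whitney with a warning.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")

    def _shapiro_p(v):
        if np.ptp(v) == 0:
            warnings.warn("constant sample: Shapiro undefined, gating to Mann-Whitney", stacklevel=3)
            return 0.0
        return float(sps.shapiro(v).pvalue)

    sp1, sp2 = _shapiro_p(x), _shapiro_p(y)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        lev_p = 1.0 if np.ptp(np.concatenate([x, y])) == 0 else 0.0
    else:
        lev_p = float(sps.levene(x, y).pvalue)

    if sp1 > alpha and sp2 > alpha and lev_p > alpha:
        res = sps.ttest_ind(x, y)
        used = "t_test"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        used = "mann_whitney"
    return TwoSampleResult(
        test_used=used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(x),
        n2=len(y),
        shapiro_p=(sp1, sp2),
        levene_p=lev_p,
    )


def profile_anova(
    profiles_by_genotype: dict[str, list],
    window_nm: float = 200.0,
    channel: str | None = None,
) -> ProfileAnovaResult:
    """Two-way ANOVA (genotype x position) on aligned per-synapse profiles.

    ``profiles_by_genotype`` maps genotype to a list of aligned profiles;
    each profile is either a ``(positions, intensities)`` pair of arrays or
    a :class:`stedview.profiling.LineProfile` (then ``channel`` selects the
    intensity channel and positions must already be scaffold-peak
    centered).  Only positions with \\|pos\\| <= window_nm/2 enter the model;
    position is treated as categorical and the interaction is included.
    The genotype main effect is the headline value.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    n_per: dict[str, int] = {}
    for geno, profiles in profiles_by_genotype.items():
        if len(profiles) < 2:
            raise ValueError(f"genotype {geno!r} needs >= 2 profiles")
        n_per[geno] = len(profiles)
        for i, p in enumerate(profiles):
            if hasattr(p, "positions"):
                pos, inten = np.asarray(p.positions), np.asarray(p.intensities[channel])
            else:
                pos, inten = np.asarray(p[0], dtype=float), np.asarray(p[1], dtype=float)
            keep = np.abs(pos) <= window_nm / 2.0 + 1e-9
            if not keep.any():
                raise ValueError("profile does not span the analysis window")
            for q, v in zip(pos[keep], inten[keep]):
                rows.append({"genotype": geno, "position": round(float(q), 6), "intensity": float(v)})
    df = pd.DataFrame(rows)

    y = df["intensity"].to_numpy()
    cell_means = df.groupby(["genotype", "position"])["intensity"].transform("mean").to_numpy()
    ss_resid = float(((y - cell_means) ** 2).sum())
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_resid <= 1e-12 * max(1.0, ss_total):
        # no within-cell variance: each effect is either exactly absent
        # (F = 0, p = 1) or unbounded (flagged infinite, p = 0)
        warnings.warn("zero residual variance: degenerate ANOVA", stacklevel=2)
        grand = y.mean()
        gm = df.groupby("genotype")["intensity"].mean()
        pm = df.groupby("position")["intensity"].mean()
        cm = df.groupby(["genotype", "position"])["intensity"].mean()
        nc = df.groupby(["genotype", "position"]).size()
        ng = df.groupby("genotype").size()
        npos = df.groupby("position").size()
        ss_g = float((ng * (gm - grand) ** 2).sum())
        ss_p = float((npos * (pm - grand) ** 2).sum())
        ss_i = float(
            sum(
                nc[g, q] * (cm[g, q] - gm[g] - pm[q] + grand) ** 2
                for g, q in cm.index
            )
        )
        tol = 1e-10 * max(1.0, ss_total)
        F = [np.inf if s > tol else 0.0 for s in (ss_g, ss_p, ss_i)]
        p = [0.0 if np.isinf(f) else 1.0 for f in F]
        table = pd.DataFrame(
            {"F": F, "p": p, "df": [np.nan] * 3},
            index=["genotype", "position", "interaction"],
        )
        return ProfileAnovaResult(window_nm, table, n_per, degenerate=True)

    model = ols("intensity ~ C(genotype) * C(position)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    table = pd.DataFrame(
        {
            "F": [
                aov.loc["C(genotype)", "F"],
                aov.loc["C(position)", "F"],
                aov.loc["C(genotype):C(position)", "F"],
            ],
            "p": [
                aov.loc["C(genotype)", "PR(>F)"],
                aov.loc["C(position)", "PR(>F)"],
                aov.loc["C(genotype):C(position)", "PR(>F)"],
            ],
            "df": [
                aov.loc["C(genotype)", "df"],
                aov.loc["C(position)", "df"],
                aov.loc["C(genotype):C(position)", "df"],
            ],
        },
        index=["genotype", "position", "interaction"],
    )
    return ProfileAnovaResult(window_nm, table, n_per)


def summarize(values) -> tuple[float, float, int]:
    """Mean, SEM (sample SD / sqrt(n)) and n; SEM is NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return mean, sem, n
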