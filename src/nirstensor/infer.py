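"""Component-wise 2x2 ANOVA, profile summation, TOI/ROI determination, and
Bayes-factor follow-up.

Each component of a decomposition carries a subject-score vector (the
subject-mode loading). A 2x2 ANOVA on those scores — fully between-subjects
(Type III sums of squares, robust to unbalanced cells) or mixed-model —
flags the components whose expression differs by entity type, action
sequence, or their interaction. Significant components are summed (absolute
values, weighted by cross-run occurrence for the CPD) into temporal,
spatial and spectral profiles per effect; the temporal profile's
within-stimulus peak defines the TOI, the dominant channels of the spatial
profile the ROI. JZS Bayes-factor t tests on the mean HbO inside the
TOI x ROI window quantify the simple effects behind an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .core_io import ConfigurationError, DataError, DesignInfo, EpochDefinition, SubjectHRF
from .decompose import CPDModel, TuckerModel

__all__ = [
    "EffectTestResult",
    "TDComponent",
    "ProfileSet",
    "TOIROIResult",
    "BayesResult",
    "subject_scores_cpd",
    "subject_scores_td",
    "anova_2x2_between",
    "anova_2x2_mixed",
    "anova_on_scores",
    "select_and_sum",
    "determine_toi",
    "determine_roi",
    "bayes_followup",
]

EFFECTS = ("main_a", "main_b", "interaction")


@dataclass
class EffectTestResult:
    """F and p for both main effects and the interaction of one component."""

    component: object  # ComponentRef-like or (rt, rc) tuple
    effects: dict[str, tuple[float, float]]  # effect -> (F, p)
    hemisphere: str = ""

    def __post_init__(self) -> None:
        for name, (f, p) in self.effects.items():
            if f < 0 or not (0 <= p <= 1):
                raise DataError(f"invalid F/p for {name}: F={f}, p={p}")


@dataclass(frozen=True)
class TDComponent:
    """One (temporal, spatial) component combination of a Tucker model.

    ``magnitude`` carries the combination's energy in the decomposition (the
    core-fiber norm); profile summation scales by it so a marginally
    significant noise combination cannot outweigh the dominant one.
    """

    rt: int
    rc: int
    temporal: np.ndarray
    spatial: np.ndarray
    spectral: np.ndarray | None = None
    occurrence_weight: float = 1.0
    magnitude: float = 1.0


@dataclass
class ProfileSet:
    """Summed significant component profiles for one effect and hemisphere."""

    effect: str
    hemisphere: str
    temporal_profile: np.ndarray
    spatial_profile: np.ndarray
    spectral_profile: np.ndarray | None
    times_s: np.ndarray
    channel_ids: list[str]
    freqs_hz: np.ndarray | None = None
    n_significant: int = 0
    weighted_count: float = 0.0
    contributors: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.n_significant == 0


@dataclass
class BayesResult:
    """One follow-up contrast: BF10 with the cell statistics behind it."""

    contrast: str
    bf10: float
    t: float
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    paired: bool


@dataclass
class TOIROIResult:
    """Discovered time window and channel set for one significant effect."""

    effect: str
    hemisphere: str
    toi: tuple[float, float] | None
    roi: list[str]
    peak_time_s: float | None
    followup: list[BayesResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# subject scores
# ---------------------------------------------------------------------------


def subject_scores_cpd(model: CPDModel, r: int) -> np.ndarray:
    """Subject-mode column r scaled by the component weight lambda_r."""
    if not (0 <= r < model.rank):
        raise IndexError(f"component index {r} out of range for rank {model.rank}")
    return model.factors[-1][:, r] * model.weights[r]


def subject_scores_td(model: TuckerModel, rt: int, rc: int) -> np.ndarray:
    """Scores of the (rt, rc) combination: A(s) applied to the core fiber."""
    r_t, r_c, _ = model.core.shape
    if not (0 <= rt < r_t) or not (0 <= rc < r_c):
        raise IndexError(f"combination ({rt}, {rc}) out of range for core {model.core.shape}")
    return model.factors[2] @ model.core[rt, rc, :]


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _scores_frame(
    scores: np.ndarray, subject_conditions: list[tuple[str, tuple[str, str]]]
) -> pd.DataFrame:
    if len(scores) != len(subject_conditions):
        raise DataError("scores and subject slots differ in length")
    return pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "subject": [sid for sid, _ in subject_conditions],
            "a": [cell[0] for _, cell in subject_conditions],
            "b": [cell[1] for _, cell in subject_conditions],
        }
    )


def anova_2x2_between(
    scores: np.ndarray,
    design: DesignInfo,
    subject_conditions: list[tuple[str, tuple[str, str]]],
) -> EffectTestResult:
    """Two-way between-subjects ANOVA with Type III sums of squares.

    Type III (sum-to-zero contrasts) keeps the main-effect tests meaningful
    for unbalanced cell counts.
    """
    if design.is_mixed:
        raise ConfigurationError("use anova_2x2_mixed for designs with a within factor")
    frame = _scores_frame(scores, subject_conditions)
    cells = frame.groupby(["a", "b"], observed=True).size()
    if len(cells) < 4 or (cells < 2).any():
        raise DataError(f"every design cell needs >= 2 subjects; got\n{cells}")
    fit = ols("score ~ C(a, Sum) * C(b, Sum)", data=frame).fit()
    table = anova_lm(fit, typ=3)
    effects = {
        "main_a": (float(table.loc["C(a, Sum)", "F"]), float(table.loc["C(a, Sum)", "PR(>F)"])),
        "main_b": (float(table.loc["C(b, Sum)", "F"]), float(table.loc["C(b, Sum)", "PR(>F)"])),
        "interaction": (
            float(table.loc["C(a, Sum):C(b, Sum)", "F"]),
            float(table.loc["C(a, Sum):C(b, Sum)", "PR(>F)"]),
        ),
    }
    effects = {k: (max(f, 0.0), min(max(p, 0.0), 1.0)) for k, (f, p) in effects.items()}
    return EffectTestResult(component=None, effects=effects)


def anova_2x2_mixed(
    scores: np.ndarray,
    design: DesignInfo,
    subject_conditions: list[tuple[str, tuple[str, str]]],
) -> EffectTestResult:
    """Mixed-model 2x2 ANOVA (one within-, one between-subjects factor).

    The between effect is tested against the between-subject mean square,
    the within effect and interaction against the within-subject error
    (classic univariate mixed ANOVA, as implemented by pingouin).
    """
    within = design.within_factor
    if within is None:
        raise ConfigurationError("use anova_2x2_between for fully between designs")
    frame = _scores_frame(scores, subject_conditions)
    counts = frame.groupby("subject", observed=True).size()
    if (counts != 2).any():
        raise DataError("every subject must contribute exactly one score per within level")
    within_col, between_col = ("a", "b") if within == "a" else ("b", "a")
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.mixed_anova(
            data=frame, dv="score", within=within_col, subject="subject", between=between_col
        )
    aov = aov.set_index("Source")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"

    def _fp(row) -> tuple[float, float]:
        f, p = float(row["F"]), float(row[p_col])
        if not np.isfinite(f):  # 0/0 when neither effect nor error variance
            return 0.0, 1.0
        return max(f, 0.0), min(max(p, 0.0), 1.0) if np.isfinite(p) else 1.0

    by_factor = {
        within_col: _fp(aov.loc[within_col]),
        between_col: _fp(aov.loc[between_col]),
    }
    effects = {
        "main_a": by_factor["a"],
        "main_b": by_factor["b"],
        "interaction": _fp(aov.loc["Interaction"]),
    }
    return EffectTestResult(component=None, effects=effects)


def anova_on_scores(
    scores: np.ndarray,
    design: DesignInfo,
    subject_conditions: list[tuple[str, tuple[str, str]]],
) -> EffectTestResult:
    """Dispatch to the between or mixed ANOVA according to the design."""
    if design.is_mixed:
        return anova_2x2_mixed(scores, design, subject_conditions)
    return anova_2x2_between(scores, design, subject_conditions)


# ---------------------------------------------------------------------------
# profile summation and TOI/ROI
# ---------------------------------------------------------------------------


def select_and_sum(
    results: list[EffectTestResult],
    components: list,
    alpha: float,
    hemisphere: str,
    times_s: np.ndarray,
    channel_ids: list[str],
    freqs_hz: np.ndarray | None = None,
    fdr_correction: bool = False,
) -> dict[str, ProfileSet]:
    """Sum the absolute profiles of significant components, per effect.

    ``results[i]`` must test ``components[i]``; each component exposes
    ``temporal``, ``spatial``, optional ``spectral`` vectors and an
    ``occurrence_weight`` (1 for Tucker combinations). Summation commutes,
    so the outcome is invariant to component order. Optional
    Benjamini-Hochberg correction adjusts the p values within each effect
    across components (off by default, matching per-test alpha).
    """
    if len(results) != len(components):
        raise DataError("results and components must align")
    out: dict[str, ProfileSet] = {}
    for effect in EFFECTS:
        pvals = np.array([res.effects[effect][1] for res in results]) if results else np.array([])
        if fdr_correction and pvals.size:
            significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        else:
            significant = pvals < alpha
        temporal = np.zeros_like(np.asarray(times_s, dtype=float))
        spatial = np.zeros(len(channel_ids))
        spectral = np.zeros(len(freqs_hz)) if freqs_hz is not None else None
        contributors = []
        weighted = 0.0
        for comp, sig in zip(components, significant):
            if not sig:
                continue
            occ = float(getattr(comp, "occurrence_weight", 1.0))
            w = occ * float(getattr(comp, "magnitude", 1.0))
            temporal += w * np.abs(comp.temporal)
            spatial += w * np.abs(comp.spatial)
            if spectral is not None and getattr(comp, "spectral", None) is not None:
                spectral += w * np.abs(comp.spectral)
            contributors.append((comp, w))
            weighted += occ
        out[effect] = ProfileSet(
            effect=effect,
            hemisphere=hemisphere,
            temporal_profile=temporal,
            spatial_profile=spatial,
            spectral_profile=spectral,
            times_s=np.asarray(times_s, dtype=float),
            channel_ids=list(channel_ids),
            freqs_hz=None if freqs_hz is None else np.asarray(freqs_hz, dtype=float),
            n_significant=len(contributors),
            weighted_count=weighted,
            contributors=contributors,
        )
    return out


def determine_toi(
    profile: ProfileSet,
    epoch: EpochDefinition,
    half_width_s: float = 1.0,
    post_fraction: float = 0.5,
) -> tuple[tuple[float, float] | None, float | None]:
    """Locate the TOI as the within-stimulus peak of the temporal profile.

    A peak occurring after stimulus offset is not a TOI: when the global
    maximum lies post-stimulus and no within-stimulus value reaches
    ``post_fraction`` of it, no TOI is returned. Ties resolve to the
    earliest peak. The reported window is the peak +/- ``half_width_s``,
    clipped to the stimulus period.
    """
    if profile.empty or not np.any(profile.temporal_profile):
        return None, None
    times = profile.times_s
    values = profile.temporal_profile
    stim_mask = (times >= 0.0) & (times < epoch.stimulus_s)
    if not np.any(stim_mask):
        return None, None
    stim_idx = np.nonzero(stim_mask)[0]
    best_in = stim_idx[int(np.argmax(values[stim_mask]))]
    global_best = int(np.argmax(values))
    if times[global_best] >= epoch.stimulus_s and values[best_in] < post_fraction * values[global_best]:
        return None, None
    peak_t = float(times[best_in])
    toi = (max(0.0, peak_t - half_width_s), min(epoch.stimulus_s, peak_t + half_width_s))
    return toi, peak_t


def determine_roi(profile: ProfileSet, fraction_of_max: float = 0.5) -> list[str]:
    """Channels whose spatial-profile value reaches a fraction of the maximum."""
    if profile.empty or not np.any(profile.spatial_profile):
        return []
    cutoff = fraction_of_max * float(np.max(profile.spatial_profile))
    return [ch for ch, v in zip(profile.channel_ids, profile.spatial_profile) if v >= cutoff]


# ---------------------------------------------------------------------------
# Bayes-factor follow-up
# ---------------------------------------------------------------------------


def _window_means(
    hrfs: list[SubjectHRF],
    toi: tuple[float, float],
    roi: list[str],
    pad_s: float = 1.0,
) -> dict[tuple[str, tuple[str, str]], float]:
    """Mean HbO over [toi.start - pad, toi.end + pad] x ROI, per subject/condition."""
    out: dict[tuple[str, tuple[str, str]], float] = {}
    for h in hrfs:
        times = h.epoch.times()
        mask = (times >= toi[0] - pad_s) & (times <= toi[1] + pad_s)
        cols = [h.channel_ids.index(ch) for ch in roi if ch in h.channel_ids]
        if not cols:
            raise DataError("ROI channels absent from the supplied HRFs")
        out[(h.subject_id, tuple(h.condition))] = float(h.hrf[np.ix_(mask, cols)].mean())
    return out


def _jzs_bf(t: float, nx: int, ny: int | None, paired: bool, r_scale: float) -> float:
    return float(pg.bayesfactor_ttest(t, nx, ny, paired=paired, r=r_scale))


def bayes_followup(
    hrfs: list[SubjectHRF],
    toi: tuple[float, float],
    roi: list[str],
    design: DesignInfo,
    contrasts: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    prior_scale: float = 0.707,
    pad_s: float = 1.0,
) -> list[BayesResult]:
    """JZS Bayes-factor t tests on TOI x ROI means for simple-effect contrasts.

    By default the factor-A difference is tested within each level of B (the
    standard decomposition of an A x B interaction). Between-subjects
    contrasts use a two-sample test; if factor A is within-subjects the two
    conditions are paired by subject id. The Cauchy prior scale defaults to
    0.707.
    """
    if toi is None:
        raise ConfigurationError("bayes_followup requires a TOI")
    means = _window_means(hrfs, toi, roi, pad_s)
    if contrasts is None:
        contrasts = [
            ((design.levels_a[0], lb), (design.levels_a[1], lb)) for lb in design.levels_b
        ]
    paired = design.within_factor == "a"
    results: list[BayesResult] = []
    for cell1, cell2 in contrasts:
        g1 = {sid: v for (sid, cell), v in means.items() if cell == tuple(cell1)}
        g2 = {sid: v for (sid, cell), v in means.items() if cell == tuple(cell2)}
        pair_within = paired and cell1[1] == cell2[1]
        if pair_within:
            shared = sorted(set(g1) & set(g2))
            if len(shared) < 2:
                raise DataError(f"fewer than 2 paired subjects for contrast {cell1} vs {cell2}")
            x = np.array([g1[s] for s in shared])
            y = np.array([g2[s] for s in shared])
            t_stat = stats.ttest_rel(x, y).statistic
            bf = _jzs_bf(float(t_stat), len(shared), None, True, prior_scale)
            n1 = n2 = len(shared)
        else:
            x = np.array(sorted(g1.values()))
            y = np.array(sorted(g2.values()))
            if len(x) < 2 or len(y) < 2:
                raise DataError(f"fewer than 2 subjects per cell for contrast {cell1} vs {cell2}")
            t_stat = stats.ttest_ind(x, y).statistic
            bf = _jzs_bf(float(t_stat), len(x), len(y), False, prior_scale)
            n1, n2 = len(x), len(y)
        results.append(
            BayesResult(
                contrast=f"{'|'.join(cell1)} vs {'|'.join(cell2)}",
                bf10=bf,
                t=float(t_stat),
                n1=n1,
                n2=n2,
                mean1=float(np.mean(x)),
                sd1=float(np.std(x, ddof=1)),
                mean2=float(np.mean(y)),
                sd2=float(np.std(y, ddof=1)),
                paired=pair_within,
            )
        )
    return results
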