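"""Grand-averaging baseline: mean over a predefined TOI, then ROI, then ANOVA.

This is the conventional analysis the tensor pipeline is compared against.
It requires the TOI window and ROI channel set up front — precisely the
assumption the tensor method avoids — and collapses the temporal and
spatial structure of the response to a single value per subject/condition
before testing.
"""

from __future__ import annotations

import numpy as np

from .core_io import ConfigurationError, DesignInfo, SubjectHRF
from .infer import EffectTestResult, anova_on_scores

__all__ = ["grand_average", "grandavg_test"]


def grand_average(
    hrfs: list[SubjectHRF],
    toi_window: tuple[float, float],
    roi: list[str],
) -> list[tuple[str, tuple[str, str], float]]:
    """One spatial mean per subject/condition: TOI average, then ROI average.

    The TOI window is inclusive of both endpoints on the epoch time grid;
    channel averaging follows temporal averaging (the two steps commute for
    complete windows, but the published order is kept).
    """
    if not roi:
        raise ConfigurationError("ROI must contain at least one channel")
    out: list[tuple[str, tuple[str, str], float]] = []
    for h in hrfs:
        times = h.epoch.times()
        mask = (times >= toi_window[0]) & (times <= toi_window[1])
        if not np.any(mask):
            raise ConfigurationError(
                f"TOI window {toi_window} contains no samples of the epoch time grid"
            )
        cols = []
        for ch in roi:
            if ch not in h.channel_ids:
                raise ConfigurationError(f"ROI channel {ch!r} absent from HRF channels")
            cols.append(h.channel_ids.index(ch))
        temporal_means = h.hrf[mask].mean(axis=0)  # per channel
        spatial_mean = float(temporal_means[cols].mean())
        out.append((h.subject_id, tuple(h.condition), spatial_mean))
    return out


def grandavg_test(
    spatial_means: list[tuple[str, tuple[str, str], float]],
    design: DesignInfo,
) -> EffectTestResult:
    """2x2 ANOVA (between or mixed per the design) on the spatial means."""
    scores = np.array([v for _, _, v in spatial_means])
    slots = [(sid, cell) for sid, cell, _ in spatial_means]
    return anova_on_scores(scores, design, slots)
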