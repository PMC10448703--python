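"""Synthetic multi-subject fNIRS datasets with planted TOI/ROI effects.

The generator emulates the study conditions downstream stages expect:
trial-averaged HbO responses over 20 channels (10 per hemisphere), epochs of
2 s baseline / 12-15 s stimulus / 10 s post-stimulus, 12 trials per subject,
and a 2x2 between-subjects or mixed design. Condition effects are planted as
double-gamma hemodynamic bumps confined to a ground-truth time window and
channel set, on top of white measurement noise and a slow sinusoidal drift
standing in for systemic physiology.

Randomness contract: one master seed; each subject draws from a substream
keyed ``(seed, subject_index)`` so growing ``n_subjects_per_cell`` never
reshuffles existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .core_io import (
    ConfigurationError,
    DesignInfo,
    EpochDefinition,
    FNIRSRecording,
    default_hemisphere_map,
)

__all__ = ["EffectSpec", "SimulationSpec", "GroundTruth", "canonical_hrf", "simulate_dataset"]

EffectName = Literal["main_a", "main_b", "interaction"]

DRIFT_PERIOD_S = 30.0  # slow systemic oscillation stood in for physiology
TRIAL_GAP_S = 2.0      # inter-trial interval beyond the epoch itself


@dataclass(frozen=True)
class EffectSpec:
    """A planted condition effect localized in time and channel.

    ``cell_pattern`` maps each design cell ``(level_a, level_b)`` to an
    amplitude multiplier; the planted bump in a cell has peak amplitude
    ``amplitude_delta * cell_pattern[cell]`` (micromolar). For a pure main
    effect of A use ``{(a1,*): 1, (a2,*): 0}``; an interaction requires a
    non-additive pattern such as ``{(a1,b1): 1, others: 0}``.
    """

    effect: EffectName
    channels: tuple[str, ...]
    window_s: tuple[float, float]
    amplitude_delta: float
    cell_pattern: dict[tuple[str, str], float]

    def amplitude(self, cell: tuple[str, str]) -> float:
        return self.amplitude_delta * self.cell_pattern.get(tuple(cell), 0.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic dataset."""

    n_subjects_per_cell: int = 5
    epoch: EpochDefinition = field(default_factory=EpochDefinition)
    n_channels: int = 20
    n_trials: int = 12
    effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 0.3    # per-sample white noise, micromolar
    drift_amp: float = 0.1   # slow sinusoid amplitude, micromolar
    seed: int = 0
    factor_a_scope: str = "between"
    factor_b_scope: str = "between"
    levels_a: tuple[str, str] = ("a1", "a2")
    levels_b: tuple[str, str] = ("b1", "b2")

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ConfigurationError("noise_sd and drift_amp must be >= 0")
        if self.n_subjects_per_cell < 1:
            raise ConfigurationError("n_subjects_per_cell must be >= 1")

    @property
    def channel_ids(self) -> list[str]:
        return [f"ch{i + 1}" for i in range(self.n_channels)]


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    effects: list[EffectSpec]
    design: DesignInfo
    epoch: EpochDefinition
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "epoch": asdict(self.epoch),
            "design": {
                "factor_a_scope": self.design.factor_a_scope,
                "factor_b_scope": self.design.factor_b_scope,
                "levels_a": list(self.design.levels_a),
                "levels_b": list(self.design.levels_b),
                "subject_assignments": {k: list(v) for k, v in self.design.subject_assignments.items()},
            },
            "effects": [
                {
                    "effect": e.effect,
                    "channels": list(e.channels),
                    "window_s": list(e.window_s),
                    "amplitude_delta": e.amplitude_delta,
                    "cell_pattern": {"|".join(k): v for k, v in e.cell_pattern.items()},
                }
                for e in self.effects
            ],
        }


def canonical_hrf(
    duration_s: float,
    fs: float,
    peak_s: float = 6.0,
    undershoot_ratio: float = 0.167,
) -> np.ndarray:
    """Unit-peak double-gamma hemodynamic response surrogate.

    A gamma-like rise ``(t/p)^(p/b) exp(-(t-p)/b)`` peaking exactly at
    ``peak_s``, minus a delayed copy scaled by ``undershoot_ratio``; the
    result is renormalized so its maximum is exactly 1.0. With
    ``undershoot_ratio=0`` the curve is everywhere nonnegative.
    """
    if not (duration_s > peak_s > 0):
        raise ConfigurationError("require duration_s > peak_s > 0")
    if fs <= 0:
        raise ConfigurationError("fs must be > 0")
    t = np.arange(int(round(duration_s * fs)) + 1) / fs
    b = max(0.9, peak_s / 8.0)  # dispersion; wider responses for longer peaks

    def bump(p: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(t > 0, np.power(t / p, p / b) * np.exp(-(t - p) / b), 0.0)
        return out

    undershoot_peak = min(peak_s * 2.0, 0.5 * (peak_s + duration_s))
    curve = bump(peak_s) - undershoot_ratio * bump(undershoot_peak)
    return curve / np.max(curve)


def _design_from_spec(spec: SimulationSpec) -> DesignInfo:
    assignments: dict[str, tuple[str, str]] = {}
    idx = 0
    if spec.factor_a_scope == "within":
        # each between-level of B gets a group; subjects see both A levels
        for lb in spec.levels_b:
            for _ in range(spec.n_subjects_per_cell):
                assignments[f"s{idx + 1:03d}"] = ("*", lb)
                idx += 1
    else:
        for la in spec.levels_a:
            for lb in spec.levels_b:
                for _ in range(spec.n_subjects_per_cell):
                    assignments[f"s{idx + 1:03d}"] = (la, lb)
                    idx += 1
    return DesignInfo(
        factor_a_scope=spec.factor_a_scope,
        factor_b_scope=spec.factor_b_scope,
        levels_a=spec.levels_a,
        levels_b=spec.levels_b,
        subject_assignments=assignments,
    )


def _trial_signal(spec: SimulationSpec, cell: tuple[str, str]) -> np.ndarray:
    """Noise-free epoch (time x channel) for one trial in the given cell."""
    epoch = spec.epoch
    n = epoch.n_samples
    signal = np.zeros((n, spec.n_channels))
    ch_index = {ch: j for j, ch in enumerate(spec.channel_ids)}
    for eff in spec.effects:
        unknown = [ch for ch in eff.channels if ch not in ch_index]
        if unknown:
            raise ConfigurationError(f"effect references nonexistent channels {unknown}")
        start_s, end_s = eff.window_s
        if not (0 <= start_s < end_s <= epoch.stimulus_s):
            raise ConfigurationError(
                f"effect window {eff.window_s} must lie within the stimulus period"
            )
        amp = eff.amplitude(cell)
        if amp == 0.0:
            continue
        width = end_s - start_s
        bump = amp * canonical_hrf(width, epoch.fs, peak_s=width / 2.0, undershoot_ratio=0.0)
        i0 = epoch.n_baseline + int(round(start_s * epoch.fs))
        sl = slice(i0, min(i0 + bump.size, n))
        for ch in eff.channels:
            signal[sl, ch_index[ch]] += bump[: sl.stop - sl.start]
    return signal


def simulate_dataset(spec: SimulationSpec) -> tuple[list[FNIRSRecording], GroundTruth]:
    """Generate one recording per subject plus the planted ground truth.

    Per trial, the signal is the cell's planted bump(s) in the effect
    channels, superimposed on a per-subject/channel sinusoidal drift and
    white Gaussian noise. Deterministic given ``spec.seed``.
    """
    design = _design_from_spec(spec)
    epoch = spec.epoch
    fs = epoch.fs
    trial_stride = int(round((epoch.total_s + TRIAL_GAP_S) * fs))
    n_total = epoch.n_baseline + spec.n_trials * trial_stride + int(round(fs))
    hemisphere_map = default_hemisphere_map(spec.channel_ids)

    recordings: list[FNIRSRecording] = []
    for subj_idx, (sid, cell) in enumerate(sorted(design.subject_assignments.items())):
        rng = np.random.default_rng([spec.seed, subj_idx])
        hbo = rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, n_total)) if spec.noise_sd > 0 else np.zeros((spec.n_channels, n_total))
        if spec.drift_amp > 0:
            t = np.arange(n_total) / fs
            phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
            hbo += spec.drift_amp * np.sin(
                2 * np.pi * t[None, :] / DRIFT_PERIOD_S + phases[:, None]
            )

        # trial layout: for a within factor A, a block of n/2 trials per level
        if design.factor_a_scope == "within":
            half = spec.n_trials // 2
            trial_cells = [(spec.levels_a[0], cell[1])] * half + [(spec.levels_a[1], cell[1])] * (
                spec.n_trials - half
            )
        else:
            trial_cells = [cell] * spec.n_trials

        onsets: list[tuple[int, str]] = []
        for k, trial_cell in enumerate(trial_cells):
            onset = epoch.n_baseline + k * trial_stride + epoch.n_baseline
            signal = _trial_signal(spec, trial_cell)
            start = onset - epoch.n_baseline
            hbo[:, start : start + epoch.n_samples] += signal.T
            onsets.append((onset, "|".join(trial_cell)))

        recordings.append(
            FNIRSRecording(
                subject_id=sid,
                hbo=hbo,
                fs=fs,
                trial_onsets=onsets,
                channel_ids=spec.channel_ids,
                hemisphere_map=hemisphere_map,
            )
        )
    truth = GroundTruth(effects=list(spec.effects), design=design, epoch=epoch, seed=spec.seed)
    return recordings, truth
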