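"""Epoching, trial averaging, resampling and hemisphere splitting.

Turns continuous recordings into trial-averaged, epoch-aligned
:class:`~nirstensor.core_io.SubjectHRF` objects at a common sampling rate.
Each epoch is baseline-corrected by subtracting its 2-s pre-onset mean per
channel before averaging; the post-stimulus period is interpreted as the
10 s following stimulus *offset*.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core_io import (
    ConfigurationError,
    DataError,
    DesignInfo,
    EpochDefinition,
    FNIRSRecording,
    SubjectHRF,
)

__all__ = ["build_hrf", "resample_hrf", "split_hemispheres"]


def _condition_of(label: str, design: DesignInfo, subject_cell: tuple[str, str]) -> tuple[str, str]:
    """Resolve a trial label into a full (level_a, level_b) cell."""
    parts = label.split("|")
    if len(parts) == 2:
        la, lb = parts
    elif len(parts) == 1:
        # single-level label names the within-factor level; the between level
        # comes from the subject's assignment
        if design.within_factor == "a":
            la, lb = parts[0], subject_cell[1]
        elif design.within_factor == "b":
            la, lb = subject_cell[0], parts[0]
        else:
            raise DataError(f"trial label {label!r} does not name both factor levels")
    else:
        raise DataError(f"unparseable trial label {label!r}")
    if la not in design.levels_a and la != "*":
        raise DataError(f"unknown level_a {la!r} in trial label {label!r}")
    if lb not in design.levels_b and lb != "*":
        raise DataError(f"unknown level_b {lb!r} in trial label {label!r}")
    return la, lb


def build_hrf(
    recording: FNIRSRecording,
    epoch: EpochDefinition,
    design: DesignInfo,
    baseline_correct: bool = True,
) -> list[SubjectHRF]:
    """Average the recording's trials into one HRF per condition present.

    Epochs span ``[onset - baseline, onset + stimulus + post]`` (inclusive
    endpoint); each is baseline-corrected by subtracting the per-channel mean
    over the half-open baseline window ``[start, onset)``, then trials within
    the same condition are averaged arithmetically.
    """
    recording.validate_epochs(epoch)
    subject_cell = design.cell_of(recording.subject_id)
    by_condition: dict[tuple[str, str], list[np.ndarray]] = {}
    for onset, label in recording.trial_onsets:
        cell = _condition_of(label, design, subject_cell)
        start = onset - epoch.n_baseline
        ep = recording.hbo[:, start : start + epoch.n_samples].T.copy()  # time x channel
        if baseline_correct:
            ep -= ep[: epoch.n_baseline].mean(axis=0, keepdims=True)
        by_condition.setdefault(cell, []).append(ep)

    required = _required_conditions(design, subject_cell)
    missing = [cell for cell in required if cell not in by_condition]
    if missing:
        raise DataError(
            f"subject {recording.subject_id}: no trials for condition(s) {missing}"
        )

    out: list[SubjectHRF] = []
    for cell in sorted(by_condition):
        trials = by_condition[cell]
        out.append(
            SubjectHRF(
                subject_id=recording.subject_id,
                condition=cell,
                hrf=np.mean(trials, axis=0),
                epoch=epoch,
                channel_ids=list(recording.channel_ids),
                n_trials_averaged=len(trials),
            )
        )
    return out


def _required_conditions(design: DesignInfo, cell: tuple[str, str]) -> list[tuple[str, str]]:
    if design.within_factor == "a":
        return [(la, cell[1]) for la in design.levels_a]
    if design.within_factor == "b":
        return [(cell[0], lb) for lb in design.levels_b]
    return [cell]


def resample_hrf(hrf: SubjectHRF, target_fs: float, method: str = "linear") -> SubjectHRF:
    """Upsample an HRF onto the target time grid.

    Linear interpolation by default (endpoints preserved exactly); polyphase
    resampling (:func:`scipy.signal.resample_poly`) behind ``method``.
    Downsampling is out of scope and rejected.
    """
    fs = hrf.epoch.fs
    if target_fs < fs:
        raise ConfigurationError(f"downsampling ({fs} -> {target_fs} Hz) is not supported")
    if target_fs == fs:
        return hrf
    new_epoch = EpochDefinition(
        baseline_s=hrf.epoch.baseline_s,
        stimulus_s=hrf.epoch.stimulus_s,
        post_s=hrf.epoch.post_s,
        fs=target_fs,
    )
    t_old = hrf.epoch.times()
    t_new = new_epoch.times()
    if method == "linear":
        data = np.column_stack(
            [np.interp(t_new, t_old, hrf.hrf[:, j]) for j in range(hrf.hrf.shape[1])]
        )
    elif method == "polyphase":
        from fractions import Fraction

        frac = Fraction(target_fs / fs).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        data = sps.resample_poly(hrf.hrf, up, down, axis=0)[: new_epoch.n_samples]
        if data.shape[0] < new_epoch.n_samples:  # pad the trailing edge
            pad = np.repeat(data[-1:], new_epoch.n_samples - data.shape[0], axis=0)
            data = np.vstack([data, pad])
    else:
        raise ConfigurationError(f"unknown resampling method {method!r}")
    return SubjectHRF(
        subject_id=hrf.subject_id,
        condition=hrf.condition,
        hrf=data,
        epoch=new_epoch,
        channel_ids=list(hrf.channel_ids),
        n_trials_averaged=hrf.n_trials_averaged,
    )


def split_hemispheres(
    hrfs: list[SubjectHRF], hemisphere_map: dict[str, str]
) -> tuple[list[SubjectHRF], list[SubjectHRF]]:
    """Partition every HRF's channels into (left, right) sets.

    Within-hemisphere channel order follows the original channel order; the
    two partitions are disjoint and jointly exhaustive.
    """
    left_out: list[SubjectHRF] = []
    right_out: list[SubjectHRF] = []
    for hrf in hrfs:
        unmapped = [ch for ch in hrf.channel_ids if hemisphere_map.get(ch) not in ("left", "right")]
        if unmapped:
            raise ConfigurationError(f"channels without hemisphere mapping: {unmapped}")
        for hemi, sink in (("left", left_out), ("right", right_out)):
            idx = [j for j, ch in enumerate(hrf.channel_ids) if hemisphere_map[ch] == hemi]
            if not idx:
                continue
            sink.append(
                SubjectHRF(
                    subject_id=hrf.subject_id,
                    condition=hrf.condition,
                    hrf=hrf.hrf[:, idx],
                    epoch=hrf.epoch,
                    channel_ids=[hrf.channel_ids[j] for j in idx],
                    n_trials_averaged=hrf.n_trials_averaged,
                )
            )
    return left_out, right_out
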