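"""Tensor construction: per-hemisphere 4-way (CPD) and 3-way (Tucker) arrays.

The CPD tensor stacks short-time Fourier magnitude spectrograms —
(time-frame, frequency, channel, subject) — keeping positive frequencies
only so every entry is nonnegative. The Tucker tensor keeps the signed HbO
values as (time, channel, subject). In mixed designs each subject
contributes one subject-axis slot per within-factor level, so 36 subjects
x 2 levels yield a subject mode of 72.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .core_io import ConfigurationError, DataError, DesignInfo, EpochDefinition, SubjectHRF

__all__ = ["HemodynamicTensor", "stft_magnitude", "build_tensor_cpd", "build_tensor_td"]


@dataclass
class HemodynamicTensor:
    """A labeled 3- or 4-way array with per-mode coordinate vectors.

    ``mode_axes`` is ordered to match ``data``'s axes; times are seconds
    relative to stimulus onset, frequencies in Hz, channels by id, and the
    subject axis by ``subject_conditions`` slots of
    ``(subject_id, (level_a, level_b))``.
    """

    data: np.ndarray
    mode_names: tuple[str, ...]
    mode_axes: tuple[np.ndarray, ...]
    hemisphere: str
    subject_conditions: list[tuple[str, tuple[str, str]]]
    design: DesignInfo
    epoch: EpochDefinition

    def __post_init__(self) -> None:
        if self.data.ndim != len(self.mode_axes) or self.data.ndim != len(self.mode_names):
            raise DataError("mode metadata do not match tensor order")
        for ax, (name, coords) in enumerate(zip(self.mode_names, self.mode_axes)):
            if self.data.shape[ax] != len(coords):
                raise DataError(f"axis {name!r}: {self.data.shape[ax]} != {len(coords)} coords")
        if len(self.subject_conditions) != self.data.shape[-1]:
            raise DataError("subject axis does not match subject_conditions")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[-1]


def stft_magnitude(
    x: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    overlap_frac: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude spectrogram of one channel at positive frequencies.

    Returns ``(mag, times, freqs)`` where ``mag`` is time-frame x frequency,
    frames are fully contained in the signal (no zero-padded edges), and the
    DC bin is dropped along with the negative frequencies so all retained
    coefficients are strictly positive-frequency magnitudes.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg < 4:
        raise ConfigurationError("STFT window must cover at least 4 samples")
    if not (0 <= overlap_frac < 1):
        raise ConfigurationError("overlap_frac must be in [0, 1)")
    if nperseg > x.size:
        raise ConfigurationError(
            f"STFT window ({nperseg} samples) longer than signal ({x.size})"
        )
    hop = max(1, int(round(nperseg * (1 - overlap_frac))))
    win = hann(nperseg, sym=False)
    sft = ShortTimeFFT(win, hop=hop, fs=fs, fft_mode="onesided")
    spectrum = sft.stft(x)
    # keep only slices fully inside the signal (no zero-padded borders)
    frame_centers = sft.t(x.size)  # seconds of each slice midpoint
    full = (frame_centers >= (nperseg - 1) / (2 * fs) - 1e-9) & (
        frame_centers <= (x.size - 1) / fs - (nperseg - 1) / (2 * fs) + 1e-9
    )
    mag = np.abs(spectrum[:, full]).T  # frames x freq
    times = frame_centers[full]
    freqs = sft.f
    keep = freqs > 0  # drop DC with the negative frequencies
    return mag[:, keep], times, freqs[keep]


def _check_common(hrfs: list[SubjectHRF]) -> None:
    if not hrfs:
        raise DataError("no HRFs supplied")
    epoch0, ch0 = hrfs[0].epoch, tuple(hrfs[0].channel_ids)
    for h in hrfs[1:]:
        if h.epoch != epoch0:
            raise DataError("HRFs do not share a common epoch definition")
        if tuple(h.channel_ids) != ch0:
            raise DataError("HRFs do not share a common channel set/order")


def _subject_slots(hrfs: list[SubjectHRF], design: DesignInfo) -> list[SubjectHRF]:
    """Deterministic subject-axis order: by subject id, then within-level."""
    if design.within_factor == "a":
        key = lambda h: (h.subject_id, design.levels_a.index(h.condition[0]))
    elif design.within_factor == "b":
        key = lambda h: (h.subject_id, design.levels_b.index(h.condition[1]))
    else:
        key = lambda h: (h.subject_id,)
    return sorted(hrfs, key=key)


def build_tensor_cpd(
    hrfs: list[SubjectHRF],
    design: DesignInfo,
    hemisphere: str,
    window_s: float = 10.0,
    overlap_frac: float = 0.75,
) -> HemodynamicTensor:
    """Assemble the nonnegative 4-way (time, frequency, channel, subject) tensor."""
    _check_common(hrfs)
    ordered = _subject_slots(hrfs, design)
    epoch = ordered[0].epoch
    slabs = []
    times = freqs = None
    for h in ordered:
        per_channel = []
        for j in range(h.hrf.shape[1]):
            mag, times, freqs = stft_magnitude(h.hrf[:, j], epoch.fs, window_s, overlap_frac)
            per_channel.append(mag)
        slabs.append(np.stack(per_channel, axis=-1))  # frames x freq x channel
    data = np.stack(slabs, axis=-1)  # frames x freq x channel x subject
    assert times is not None and freqs is not None
    return HemodynamicTensor(
        data=data,
        mode_names=("time", "frequency", "channel", "subject"),
        mode_axes=(
            np.asarray(times) - epoch.baseline_s,  # frame centers rel. onset
            np.asarray(freqs),
            np.asarray(ordered[0].channel_ids, dtype=object),
            np.arange(len(ordered)),
        ),
        hemisphere=hemisphere,
        subject_conditions=[(h.subject_id, h.condition) for h in ordered],
        design=design,
        epoch=epoch,
    )


def build_tensor_td(
    hrfs: list[SubjectHRF],
    design: DesignInfo,
    hemisphere: str,
) -> HemodynamicTensor:
    """Assemble the signed 3-way (time, channel, subject) tensor."""
    _check_common(hrfs)
    ordered = _subject_slots(hrfs, design)
    epoch = ordered[0].epoch
    data = np.stack([h.hrf for h in ordered], axis=-1)
    return HemodynamicTensor(
        data=data,
        mode_names=("time", "channel", "subject"),
        mode_axes=(
            epoch.times(),
            np.asarray(ordered[0].channel_ids, dtype=object),
            np.arange(len(ordered)),
        ),
        hemisphere=hemisphere,
        subject_conditions=[(h.subject_id, h.condition) for h in ordered],
        design=design,
        epoch=epoch,
    )
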