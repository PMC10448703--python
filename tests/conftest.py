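import numpy as np
import pytest

from nirstensor import (
    DesignInfo,
    EffectSpec,
    EpochDefinition,
    SimulationSpec,
    build_hrf,
    simulate_dataset,
    split_hemispheres,
)


@pytest.fixture(scope="session")
def small_epoch() -> EpochDefinition:
    """Compact epoch used throughout: 2 s baseline, 12 s stimulus, 10 s post at 10 Hz."""
    return EpochDefinition(baseline_s=2.0, stimulus_s=12.0, post_s=10.0, fs=10.0)


@pytest.fixture(scope="session")
def between_design() -> DesignInfo:
    assignments = {}
    idx = 0
    for la in ("a1", "a2"):
        for lb in ("b1", "b2"):
            for _ in range(3):
                assignments[f"s{idx:03d}"] = (la, lb)
                idx += 1
    return DesignInfo(subject_assignments=assignments)


def make_effect_spec(
    epoch: EpochDefinition,
    n_per_cell: int = 5,
    amplitude: float = 0.45,
    window=(4.0, 8.0),
    channels=("ch2", "ch4"),
    noise_sd: float = 0.3,
    seed: int = 0,
    effect: str = "main_a",
) -> SimulationSpec:
    """Planted main-effect dataset on 10 channels (5 per hemisphere)."""
    if effect == "main_a":
        pattern = {("a1", "b1"): 1.0, ("a1", "b2"): 1.0, ("a2", "b1"): 0.0, ("a2", "b2"): 0.0}
    elif effect == "interaction":
        pattern = {("a1", "b1"): 1.0, ("a1", "b2"): 0.0, ("a2", "b1"): 0.0, ("a2", "b2"): 0.0}
    else:
        pattern = {("a1", "b1"): 1.0, ("a2", "b1"): 1.0, ("a1", "b2"): 0.0, ("a2", "b2"): 0.0}
    return SimulationSpec(
        n_subjects_per_cell=n_per_cell,
        epoch=epoch,
        n_channels=10,
        n_trials=12,
        effects=(
            EffectSpec(
                effect=effect,
                channels=tuple(channels),
                window_s=tuple(window),
                amplitude_delta=amplitude,
                cell_pattern=pattern,
            ),
        ),
        noise_sd=noise_sd,
        drift_amp=0.1,
        seed=seed,
    )


@pytest.fixture()
def planted_left_hrfs(small_epoch):
    """Left-hemisphere HRFs of a small planted-main-effect dataset."""
    spec = make_effect_spec(small_epoch, n_per_cell=4, seed=5)
    recordings, truth = simulate_dataset(spec)
    hrfs = []
    for rec in recordings:
        hrfs.extend(build_hrf(rec, spec.epoch, truth.design))
    left, _ = split_hemispheres(hrfs, recordings[0].hemisphere_map)
    return left, truth
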