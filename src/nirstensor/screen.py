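"""Component screening and cross-run consensus.

Three physiological filters remove components that cannot reflect a
stimulus-locked hemodynamic response:

* **temporal** — a component whose mean absolute value from 2 s after
  stimulus onset to the end of the stimulus presentation falls below a
  threshold (default 0.01 on unit-L2-normalized vectors) only captures
  baseline activity and is dropped;
* **spectral** — a component whose peak-magnitude frequency exceeds a
  cutoff (default 0.1 Hz) is faster than hemodynamics and is dropped;
* **consensus** (CPD only) — because the CPD is run several times from
  random starts, only components whose temporal *and* spatial vectors
  correlate at r > 0.5 (p < alpha) with counterparts in other runs are
  consolidated; clusters are weighted by the fraction of runs in which
  they appear. The once-run Tucker decomposition bypasses this step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .core_io import ConfigurationError, EpochDefinition, get_logger
from .decompose import CPDModel

__all__ = [
    "ComponentRef",
    "ScreenedComponents",
    "ConsensusComponent",
    "exclude_temporal",
    "exclude_spectral",
    "screen_cpd_components",
    "match_components_across_runs",
]

logger = get_logger(__name__)


@dataclass(frozen=True)
class ComponentRef:
    """Reference to one component of one decomposition run."""

    run: int
    index: int


@dataclass
class ScreenedComponents:
    """Partition of all components into retained and excluded (with reasons)."""

    retained: list[ComponentRef]
    excluded: list[tuple[ComponentRef, str]]  # reason in {baseline_only, high_frequency}
    temporal_threshold: float
    spectral_cutoff_hz: float | None = None

    def report_rows(self) -> list[dict]:
        rows = [
            {"run": c.run, "component": c.index, "decision": "retained", "reason": ""}
            for c in self.retained
        ]
        rows += [
            {"run": c.run, "component": c.index, "decision": "excluded", "reason": reason}
            for c, reason in self.excluded
        ]
        return sorted(rows, key=lambda r: (r["run"], r["component"]))


@dataclass
class ConsensusComponent:
    """A cross-run cluster of matched CPD components.

    Vectors are unit-L2 averages of the members; ``occurrence_weight`` is the
    fraction of runs contributing at least one member; ``subject`` holds the
    averaged (weights-scaled, normalized) subject-score vectors used for the
    consensus-level ANOVA.
    """

    temporal: np.ndarray
    spatial: np.ndarray
    spectral: np.ndarray | None
    subject: np.ndarray
    occurrence_weight: float
    members: list[ComponentRef] = field(default_factory=list)


def exclude_temporal(
    temporal: np.ndarray,
    times_s: np.ndarray,
    epoch: EpochDefinition,
    threshold: float = 0.01,
) -> tuple[bool, float]:
    """Keep/drop decision on stimulus-period activity.

    Computes the mean absolute value of the (unit-L2-normalized) temporal
    vector over ``[onset + 2 s, stimulus offset)`` and keeps the component
    when it reaches ``threshold``. Returns ``(keep, statistic)``.
    """
    temporal = np.asarray(temporal, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if temporal.shape != times_s.shape:
        raise ConfigurationError("temporal vector and time axis differ in length")
    mask = (times_s >= 2.0) & (times_s < epoch.stimulus_s)
    if not np.any(mask):
        raise ConfigurationError(
            "stimulus window [onset+2 s, offset) contains no samples of the time axis"
        )
    stat = float(np.mean(np.abs(temporal[mask])))
    return stat >= threshold, stat


def exclude_spectral(
    spectral: np.ndarray,
    freqs_hz: np.ndarray,
    cutoff_hz: float = 0.1,
    statistic: str = "argmax",
) -> tuple[bool, float]:
    """Keep/drop decision on the component's dominant frequency.

    The relevance statistic is the frequency of maximum magnitude (ties go
    to the lowest frequency, numpy argmax convention) or, behind the
    ``centroid`` option, the magnitude-weighted mean frequency. Components
    with a statistic strictly above ``cutoff_hz`` are dropped. Returns
    ``(keep, peak_frequency)``.
    """
    spectral = np.asarray(spectral, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.size == 0:
        raise ConfigurationError("empty frequency axis")
    if np.any(np.diff(freqs_hz) <= 0):
        raise ConfigurationError("frequency axis must be strictly increasing")
    if statistic == "argmax":
        peak = float(freqs_hz[int(np.argmax(np.abs(spectral)))])
    elif statistic == "centroid":
        w = np.abs(spectral)
        peak = float(np.sum(w * freqs_hz) / max(np.sum(w), 1e-300))
    else:
        raise ConfigurationError(f"unknown spectral statistic {statistic!r}")
    return peak <= cutoff_hz, peak


def screen_cpd_components(
    models: list[CPDModel],
    times_s: np.ndarray,
    freqs_hz: np.ndarray,
    epoch: EpochDefinition,
    temporal_threshold: float = 0.01,
    spectral_cutoff_hz: float | None = 0.1,
    spectral_statistic: str = "argmax",
) -> ScreenedComponents:
    """Apply the temporal and spectral exclusions to every run's components.

    Screening is deterministic and per-component, so it is invariant to the
    order in which components are examined. Pass ``spectral_cutoff_hz=None``
    for 3-way models without a spectral mode.
    """
    retained: list[ComponentRef] = []
    excluded: list[tuple[ComponentRef, str]] = []
    for run, model in enumerate(models):
        for r in range(model.rank):
            ref = ComponentRef(run=run, index=r)
            keep_t, _ = exclude_temporal(
                model.factors[0][:, r], times_s, epoch, temporal_threshold
            )
            if not keep_t:
                excluded.append((ref, "baseline_only"))
                continue
            if spectral_cutoff_hz is not None:
                keep_f, _ = exclude_spectral(
                    model.factors[1][:, r], freqs_hz, spectral_cutoff_hz, spectral_statistic
                )
                if not keep_f:
                    excluded.append((ref, "high_frequency"))
                    continue
            retained.append(ref)
    return ScreenedComponents(
        retained=retained,
        excluded=excluded,
        temporal_threshold=temporal_threshold,
        spectral_cutoff_hz=spectral_cutoff_hz,
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float] | None:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def match_components_across_runs(
    models: list[CPDModel],
    retained: list[ComponentRef] | None = None,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    mode: str = "both",
) -> list[ConsensusComponent]:
    """Cluster matching components across CPD runs into consensus components.

    Components from *different* runs are linked when their temporal vectors
    and their spatial vectors (``mode="both"``; ``"either"`` relaxes to one
    of the two) correlate with r > ``r_threshold`` at p < ``alpha`` (p from
    the t transform of r with n-2 df). Connected components of this graph
    that span at least two runs become consensus components; single-run
    orphans are never promoted. Member vectors are averaged after unit-L2
    normalization (sign is fixed by the CPD's nonnegativity) and
    re-normalized; the subject vectors are scaled by the component weight
    before averaging so consensus subject scores keep their magnitude
    information.
    """
    if len(models) < 2:
        raise ConfigurationError("cross-run matching needs at least 2 runs")
    if retained is None:
        retained = [
            ComponentRef(run, r) for run, m in enumerate(models) for r in range(m.rank)
        ]
    graph = nx.Graph()
    graph.add_nodes_from(retained)
    skipped = 0
    for i, ref_a in enumerate(retained):
        for ref_b in retained[i + 1 :]:
            if ref_a.run == ref_b.run:
                continue
            ta = models[ref_a.run].factors[0][:, ref_a.index]
            tb = models[ref_b.run].factors[0][:, ref_b.index]
            sa = models[ref_a.run].factors[-2][:, ref_a.index]
            sb = models[ref_b.run].factors[-2][:, ref_b.index]
            rt = _safe_pearson(ta, tb)
            rs = _safe_pearson(sa, sb)
            if rt is None or rs is None:
                skipped += 1
                continue
            temporal_ok = rt[0] > r_threshold and rt[1] < alpha
            spatial_ok = rs[0] > r_threshold and rs[1] < alpha
            linked = (temporal_ok and spatial_ok) if mode == "both" else (temporal_ok or spatial_ok)
            if linked:
                graph.add_edge(ref_a, ref_b)
    if skipped:
        logger.warning("consensus matching skipped %d degenerate (constant) pairs", skipped)

    n_runs = len(models)
    out: list[ConsensusComponent] = []
    for cluster in nx.connected_components(graph):
        members = sorted(cluster, key=lambda c: (c.run, c.index))
        runs_present = {m.run for m in members}
        if len(runs_present) < 2:
            continue
        temporal = _unit(np.mean([_unit(models[m.run].factors[0][:, m.index]) for m in members], axis=0))
        spatial = _unit(np.mean([_unit(models[m.run].factors[-2][:, m.index]) for m in members], axis=0))
        has_spectral = len(models[members[0].run].factors) == 4
        spectral = (
            _unit(np.mean([_unit(models[m.run].factors[1][:, m.index]) for m in members], axis=0))
            if has_spectral
            else None
        )
        subject = np.mean(
            [
                models[m.run].factors[-1][:, m.index] * models[m.run].weights[m.index]
                for m in members
            ],
            axis=0,
        )
        out.append(
            ConsensusComponent(
                temporal=temporal,
                spatial=spatial,
                spectral=spectral,
                subject=subject,
                occurrence_weight=len(runs_present) / n_runs,
                members=members,
            )
        )
    out.sort(key=lambda c: (-c.occurrence_weight, c.members[0].run, c.members[0].index))
    return out
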