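import numpy as np
import pandas as pd
import pytest

from nirstensor import (
    DesignInfo,
    EpochDefinition,
    SubjectHRF,
    TDComponent,
    anova_2x2_between,
    anova_2x2_mixed,
    bayes_followup,
    determine_roi,
    determine_toi,
    select_and_sum,
    subject_scores_cpd,
    subject_scores_td,
)
from nirstensor.core_io import DataError
from nirstensor.decompose import CPDModel, TuckerModel, nn_cpd
from nirstensor.infer import EffectTestResult, ProfileSet

from _oracles import between_2x2_type3_oracle, jzs_bf10_oracle, mixed_2x2_oracle


def _between_design(n_per_cell=(5, 5, 5, 5)):
    assignments = {}
    idx = 0
    for (la, lb), n in zip(
        [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")], n_per_cell
    ):
        for _ in range(n):
            assignments[f"s{idx:03d}"] = (la, lb)
            idx += 1
    return DesignInfo(subject_assignments=assignments)


def _slots(design):
    return [(sid, cell) for sid, cell in sorted(design.subject_assignments.items())]


class TestSubjectScores:
    def test_rank1_scores_proportional_to_planted_amplitudes(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.5, 2.0, size=12)
        u = [rng.uniform(0.1, 1, size=6), rng.uniform(0.1, 1, size=5), rng.uniform(0.1, 1, size=4)]
        X = np.einsum("i,j,k,l->ijkl", u[0], u[1], u[2], amps)
        model = nn_cpd(X, 1, seed=0)
        scores = subject_scores_cpd(model, 0)
        ratio = scores / amps
        assert np.ptp(ratio) / np.mean(ratio) < 1e-6

    def test_scores_match_least_squares_projection_oracle(self):
        rng = np.random.default_rng(1)
        X = np.einsum(
            "i,j,k,l->ijkl",
            rng.uniform(0.1, 1, 7), rng.uniform(0.1, 1, 6),
            rng.uniform(0.1, 1, 5), rng.uniform(0.5, 2, 10),
        )
        model = nn_cpd(X, 1, seed=0)
        basis = np.einsum(
            "i,j,k->ijk", model.factors[0][:, 0], model.factors[1][:, 0], model.factors[2][:, 0]
        )
        proj = np.tensordot(X, basis, axes=([0, 1, 2], [0, 1, 2])) / np.sum(basis**2)
        np.testing.assert_allclose(subject_scores_cpd(model, 0), proj, rtol=1e-6)

    def test_subject_permutation_permutes_scores(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(size=(5, 4, 3, 8)))
        perm = rng.permutation(8)
        m1 = nn_cpd(X, 1, seed=3)
        m2 = nn_cpd(X[:, :, :, perm], 1, seed=3)
        np.testing.assert_allclose(
            subject_scores_cpd(m1, 0)[perm], subject_scores_cpd(m2, 0), rtol=1e-4
        )

    def test_td_identity_subject_factor_returns_core_fiber(self):
        rng = np.random.default_rng(3)
        core = rng.normal(size=(3, 2, 6))
        model = TuckerModel(
            core=core,
            factors=[np.eye(5)[:, :3], np.eye(4)[:, :2], np.eye(6)],
            ranks=(3, 2, 6),
            rel_error=0.0,
        )
        np.testing.assert_array_equal(subject_scores_td(model, 1, 0), core[1, 0, :])

    def test_td_orthogonal_subject_factor_preserves_norm(self):
        rng = np.random.default_rng(4)
        core = rng.normal(size=(2, 2, 6))
        q = np.linalg.qr(rng.normal(size=(6, 6)))[0]
        model = TuckerModel(
            core=core, factors=[np.eye(3)[:, :2], np.eye(3)[:, :2], q], ranks=(2, 2, 6),
            rel_error=0.0,
        )
        assert np.linalg.norm(subject_scores_td(model, 0, 1)) == pytest.approx(
            np.linalg.norm(core[0, 1, :])
        )

    def test_eight_by_ten_core_crosses_to_eighty_combinations(self):
        rng = np.random.default_rng(5)
        model = TuckerModel(
            core=rng.normal(size=(8, 10, 70)),
            factors=[np.eye(30)[:, :8], np.eye(10), np.eye(70)],
            ranks=(8, 10, 70),
            rel_error=0.0,
        )
        vectors = [subject_scores_td(model, i, j) for i in range(8) for j in range(10)]
        assert len(vectors) == 80

    def test_out_of_range_indices_rejected(self):
        model = TuckerModel(
            core=np.zeros((2, 2, 3)), factors=[np.eye(2), np.eye(2), np.eye(3)],
            ranks=(2, 2, 3), rel_error=0.0,
        )
        with pytest.raises(IndexError):
            subject_scores_td(model, 2, 0)


class TestBetweenANOVA:
    def test_equal_cell_means_give_zero_f(self):
        design = _between_design()
        slots = _slots(design)
        # scores depend only on position within the cell -> all cell means equal
        scores = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 4)
        res = anova_2x2_between(np.array(scores), design, slots)
        for f, _ in res.effects.values():
            assert f == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("cells", [(5, 5, 5, 5), (7, 4, 6, 5), (3, 8, 5, 4)])
    def test_matches_type3_oracle_including_unbalanced(self, cells):
        rng = np.random.default_rng(sum(cells))
        design = _between_design(cells)
        slots = _slots(design)
        scores = rng.normal(size=len(slots)) + rng.uniform(-1, 1)
        res = anova_2x2_between(scores, design, slots)
        oracle = between_2x2_type3_oracle(
            scores, [cell[0] for _, cell in slots], [cell[1] for _, cell in slots]
        )
        for effect in ("main_a", "main_b", "interaction"):
            assert res.effects[effect][0] == pytest.approx(oracle[effect], abs=1e-8, rel=1e-8)

    def test_seventy_subject_design_smoke(self):
        rng = np.random.default_rng(70)
        design = _between_design((18, 18, 17, 17))
        slots = _slots(design)
        res = anova_2x2_between(rng.normal(size=70), design, slots)
        assert set(res.effects) == {"main_a", "main_b", "interaction"}
        for f, p in res.effects.values():
            assert f >= 0 and 0 <= p <= 1

    def test_empty_cell_rejected(self):
        design = _between_design((5, 5, 5, 1))
        with pytest.raises(DataError, match=">= 2"):
            anova_2x2_between(np.zeros(16), design, _slots(design))


def _mixed_design(n_per_group=6):
    assignments = {}
    for i in range(2 * n_per_group):
        assignments[f"s{i:03d}"] = ("*", "b1" if i < n_per_group else "b2")
    return DesignInfo(factor_a_scope="within", subject_assignments=assignments)


def _mixed_slots_scores(design, rng):
    slots, scores = [], []
    for sid, cell in sorted(design.subject_assignments.items()):
        subj_effect = rng.normal()
        for la in ("a1", "a2"):
            slots.append((sid, (la, cell[1])))
            scores.append(subj_effect + rng.normal())
    return slots, np.array(scores)


class TestMixedANOVA:
    def test_identical_within_scores_give_zero_within_f(self):
        design = _mixed_design(5)
        rng = np.random.default_rng(0)
        slots, scores = [], []
        for sid, cell in sorted(design.subject_assignments.items()):
            v = rng.normal()
            for la in ("a1", "a2"):
                slots.append((sid, (la, cell[1])))
                scores.append(v)  # no within-subject difference at all
        res = anova_2x2_mixed(np.array(scores), design, slots)
        assert res.effects["main_a"][0] == pytest.approx(0.0, abs=1e-12)
        assert res.effects["interaction"][0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_manual_sums_of_squares_oracle(self, seed):
        design = _mixed_design(9)
        rng = np.random.default_rng(seed)
        slots, scores = _mixed_slots_scores(design, rng)
        res = anova_2x2_mixed(scores, design, slots)
        frame = pd.DataFrame(
            {
                "subject": [s for s, _ in slots],
                "a": [c[0] for _, c in slots],
                "b": [c[1] for _, c in slots],
                "score": scores,
            }
        )
        oracle = mixed_2x2_oracle(frame)
        assert res.effects["main_a"][0] == pytest.approx(oracle["within"], rel=1e-8)
        assert res.effects["main_b"][0] == pytest.approx(oracle["between"], rel=1e-8)
        assert res.effects["interaction"][0] == pytest.approx(oracle["interaction"], rel=1e-8)

    def test_eighteen_per_group_smoke(self):
        design = _mixed_design(18)
        rng = np.random.default_rng(18)
        slots, scores = _mixed_slots_scores(design, rng)
        res = anova_2x2_mixed(scores, design, slots)
        for f, p in res.effects.values():
            assert f >= 0 and 0 <= p <= 1

    def test_missing_within_level_rejected(self):
        design = _mixed_design(4)
        rng = np.random.default_rng(9)
        slots, scores = _mixed_slots_scores(design, rng)
        with pytest.raises(DataError, match="within level"):
            anova_2x2_mixed(scores[:-1], design, slots[:-1])


def _result(pvals):
    return EffectTestResult(
        component=None,
        effects={"main_a": (1.0, pvals[0]), "main_b": (1.0, pvals[1]), "interaction": (1.0, pvals[2])},
    )


def _component(rng, times, channels):
    return TDComponent(
        rt=0, rc=0,
        temporal=rng.normal(size=len(times)),
        spatial=rng.normal(size=len(channels)),
    )


class TestSelectAndSum:
    times = np.linspace(-2, 22, 49)
    channels = [f"ch{i}" for i in range(5)]

    def test_no_significant_components_gives_empty_profiles(self):
        rng = np.random.default_rng(0)
        comps = [_component(rng, self.times, self.channels) for _ in range(3)]
        results = [_result([0.5, 0.9, 0.2]) for _ in comps]
        profiles = select_and_sum(results, comps, 0.05, "left", self.times, self.channels)
        for p in profiles.values():
            assert p.empty and not np.any(p.temporal_profile)

    def test_single_significant_component_profiles_equal_absolute_vectors(self):
        rng = np.random.default_rng(1)
        comps = [_component(rng, self.times, self.channels)]
        results = [_result([0.01, 0.5, 0.5])]
        profiles = select_and_sum(results, comps, 0.05, "left", self.times, self.channels)
        np.testing.assert_allclose(profiles["main_a"].temporal_profile, np.abs(comps[0].temporal))
        np.testing.assert_allclose(profiles["main_a"].spatial_profile, np.abs(comps[0].spatial))
        assert profiles["main_b"].empty

    def test_summation_commutes_with_component_order(self):
        rng = np.random.default_rng(2)
        comps = [_component(rng, self.times, self.channels) for _ in range(4)]
        results = [_result([0.01, 0.2, 0.6]) for _ in comps]
        p1 = select_and_sum(results, comps, 0.05, "left", self.times, self.channels)
        p2 = select_and_sum(results[::-1], comps[::-1], 0.05, "left", self.times, self.channels)
        np.testing.assert_allclose(
            p1["main_a"].temporal_profile, p2["main_a"].temporal_profile, atol=1e-12
        )

    def test_occurrence_weights_scale_contributions(self):
        rng = np.random.default_rng(3)
        comp = _component(rng, self.times, self.channels)
        half = TDComponent(rt=0, rc=0, temporal=comp.temporal, spatial=comp.spatial,
                           occurrence_weight=0.5)
        profiles = select_and_sum(
            [_result([0.01, 1, 1])], [half], 0.05, "left", self.times, self.channels
        )
        np.testing.assert_allclose(
            profiles["main_a"].temporal_profile, 0.5 * np.abs(comp.temporal)
        )
        assert profiles["main_a"].weighted_count == pytest.approx(0.5)


def _profile(times, values, channels=("c1", "c2"), spatial=None):
    return ProfileSet(
        effect="main_a", hemisphere="left",
        temporal_profile=np.asarray(values, dtype=float),
        spatial_profile=np.asarray(spatial if spatial is not None else np.ones(len(channels))),
        spectral_profile=None, times_s=np.asarray(times), channel_ids=list(channels),
        n_significant=1,
    )


class TestTOIandROI:
    epoch = EpochDefinition(2, 15, 10, 10)

    def test_peak_at_12s_gives_window_11_to_13(self):
        times = self.epoch.times()
        values = np.exp(-0.5 * ((times - 12.0) / 1.5) ** 2)
        toi, peak = determine_toi(_profile(times, values), self.epoch)
        assert peak == pytest.approx(12.0, abs=0.11)
        assert toi[0] == pytest.approx(11.0, abs=0.11)
        assert toi[1] == pytest.approx(13.0, abs=0.11)

    def test_post_stimulus_only_peak_is_not_a_toi(self):
        times = self.epoch.times()
        values = np.where(times >= 0, np.exp(0.2 * times), 0.0)  # grows into post-stimulus
        toi, peak = determine_toi(_profile(times, values), self.epoch)
        assert toi is None and peak is None

    def test_tied_peaks_resolve_to_earlier(self):
        times = self.epoch.times()
        values = np.zeros_like(times)
        values[np.argmin(np.abs(times - 5.0))] = 1.0
        values[np.argmin(np.abs(times - 9.0))] = 1.0
        _, peak = determine_toi(_profile(times, values), self.epoch)
        assert peak == pytest.approx(5.0, abs=0.11)

    def test_dominant_channel_gives_singleton_roi(self):
        prof = _profile([0], [1], channels=("c1", "c2", "c3"), spatial=[1.0, 0.4, 0.2])
        assert determine_roi(prof, 0.5) == ["c1"]

    def test_uniform_spatial_profile_selects_all_channels(self):
        prof = _profile([0], [1], channels=("c1", "c2", "c3"), spatial=[0.7, 0.7, 0.7])
        assert determine_roi(prof, 0.5) == ["c1", "c2", "c3"]


def _hrf_for_bayes(sid, cell, value, epoch, channels=("c1", "c2")):
    data = np.full((epoch.n_samples, len(channels)), value)
    return SubjectHRF(sid, cell, data, epoch, list(channels))


class TestBayesFollowup:
    epoch = EpochDefinition(2, 12, 4, 5)

    def _dataset(self, rng, delta=0.0, n=20):
        hrfs, assignments = [], {}
        idx = 0
        for la, shift in (("a1", delta), ("a2", 0.0)):
            for lb in ("b1", "b2"):
                for _ in range(n // 2):
                    sid = f"s{idx:03d}"
                    assignments[sid] = (la, lb)
                    hrfs.append(
                        _hrf_for_bayes(sid, (la, lb), rng.normal(shift, 1.0), self.epoch)
                    )
                    idx += 1
        return hrfs, DesignInfo(subject_assignments=assignments)

    def test_null_groups_favor_h0_in_median(self):
        rng = np.random.default_rng(0)
        bfs = []
        for _ in range(100):
            hrfs, design = self._dataset(rng, delta=0.0, n=40)
            res = bayes_followup(hrfs, (5.0, 7.0), ["c1"], design)
            bfs.extend(b.bf10 for b in res)
        assert np.median(bfs) < 1.0

    def test_three_sd_separation_gives_strong_evidence(self):
        rng = np.random.default_rng(1)
        hrfs, design = self._dataset(rng, delta=3.0, n=36)
        res = bayes_followup(hrfs, (5.0, 7.0), ["c1", "c2"], design)
        for b in res:
            assert b.bf10 > 10
            assert b.bf10 == pytest.approx(
                jzs_bf10_oracle(b.t, b.n1, b.n2, paired=False), rel=1e-6
            )

    def test_exactly_equal_groups_favor_null(self):
        epoch = self.epoch
        hrfs, assignments = [], {}
        for i in range(8):
            la = "a1" if i < 4 else "a2"
            sid = f"s{i}"
            assignments[sid] = (la, "b1")
            hrfs.append(_hrf_for_bayes(sid, (la, "b1"), float(i % 4), epoch))
        design = DesignInfo(subject_assignments=assignments)
        res = bayes_followup(hrfs, (5.0, 7.0), ["c1"], design,
                             contrasts=[(("a1", "b1"), ("a2", "b1"))])
        assert res[0].t == pytest.approx(0.0, abs=1e-12)
        assert res[0].bf10 < 1.0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(2)
        hrfs, design = self._dataset(rng, n=2)
        with pytest.raises(DataError, match="fewer than 2"):
            bayes_followup(hrfs, (5.0, 7.0), ["c1"], design)
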