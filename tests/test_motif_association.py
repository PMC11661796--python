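"""Windowed gain/loss association testing: partitioning, MWU, BH, censuses."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandscan.dna import encode_many
from islandscan.motif_association import (
    association_tests,
    bh_qvalues,
    census_spacing_and_tgn,
    classify_gain,
    mwu_association,
    new_box_carriers,
    new_box_census,
    scan_associations,
    window_partition,
)
from islandscan.motif_scan import MotifHit, build_pwm
from islandscan.sortseq_io import fluorescence_scores
from islandscan.synthetic_data import ActivityModel


def exact_mwu_p(x, y):
    """Independent oracle: full permutation enumeration of the U statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(ix):
        ix = set(ix)
        xs = pooled[sorted(ix)]
        ys = pooled[[i for i in range(len(pooled)) if i not in ix]]
        return float(sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs))

    u_obs = u_stat(range(n1))
    us = np.array([u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def bh_oracle(p):
    """Reference Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestWindowPartition:
    def test_toy_fixture_partitions_by_consensus(self):
        pwm = build_pwm(["TATAAT"])
        daughters = ["GGTATAATGG"] * 3 + ["GGAGCTCAGG"] * 3
        F = np.array([3.0, 3.0, 2.0, 1.0, 1.0, 1.0])
        scores = pwm.score_positions(encode_many(daughters))[:, 2]
        F_with, F_without = window_partition(scores, F, pwm.threshold)
        assert sorted(F_with) == [2.0, 3.0, 3.0]
        assert sorted(F_without) == [1.0, 1.0, 1.0]

    def test_all_consensus_empty_without(self):
        pwm = build_pwm(["TATAAT"])
        scores = pwm.score_positions(encode_many(["TATAAT"] * 5))[:, 0]
        F_with, F_without = window_partition(scores, np.ones(5), pwm.threshold)
        assert len(F_with) == 5 and len(F_without) == 0

    def test_infinite_threshold_puts_everyone_without(self):
        pwm = build_pwm(["TATAAT"])
        scores = pwm.score_positions(encode_many(["TATAAT"] * 5))[:, 0]
        F_with, F_without = window_partition(scores, np.ones(5), np.inf)
        assert len(F_with) == 0 and len(F_without) == 5


class TestMWU:
    def test_identical_groups_p_near_one(self):
        F = np.resize([1.0, 2.0, 3.0], 20)
        p, delta = mwu_association(F, F.copy())
        assert p > 0.99
        assert delta == 0.0

    def test_complete_separation(self):
        p, delta = mwu_association(np.full(20, 3.0), np.full(20, 1.0))
        assert delta == pytest.approx(2.0)
        assert p < 1e-6

    def test_group_of_exactly_ten_skipped(self):
        assert mwu_association(np.ones(10), np.ones(30)) is None
        assert mwu_association(np.ones(11), np.ones(11)) is not None

    @given(st.integers(0, 100_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_exact_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.normal(size=int(n1))  # continuous -> no ties
        y = rng.normal(size=int(n2))
        p, _ = mwu_association(x, y, min_n=0)
        assert p == pytest.approx(exact_mwu_p(x, y), abs=1e-12)


class TestBH:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_reference_step_up(self, pvals):
        np.testing.assert_allclose(bh_qvalues(pvals), bh_oracle(pvals), atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestScanAssociations:
    def _planted(self, small_dataset):
        config, ds = small_dataset
        model = ActivityModel.from_config(config)
        pid = ds.parents[0].parent_id
        sub = ds.table[ds.table["parent_id"] == pid]
        F = fluorescence_scores(sub, "gfp").to_numpy()
        truth = ds.truth["parents"][pid]
        return model, ds.parents[0], sub["sequence"].tolist(), F, truth

    def test_planted_promoter_yields_loss_record_at_minus10(self, small_dataset):
        model, parent, seqs, F, truth = self._planted(small_dataset)
        peaks = [truth["minus10_start"] + 2]  # hotspot near the planted box
        records = scan_associations(
            parent.parent_id, parent.sequence, seqs, F, model.pwm10, peaks
        )
        at_box = [r for r in records if r.window_start == truth["minus10_start"]]
        assert at_box, "no association recorded at the planted −10 box"
        r = at_box[0]
        assert r.direction == "loss"
        assert r.delta_F > 0.5  # box carriers fluoresce higher
        assert r.effect < -0.5  # losing the box lowers fluorescence
        assert r.q <= 0.05 and r.significant_effect

    def test_flat_fluorescence_yields_no_records(self, small_dataset):
        model, parent, seqs, F, truth = self._planted(small_dataset)
        records = scan_associations(
            parent.parent_id, parent.sequence, seqs, np.full(len(seqs), 2.0),
            model.pwm10, [truth["minus10_start"]],
        )
        assert records == []

    def test_gain_record_for_new_box_downstream_of_minus35(self, small_dataset):
        """Daughters creating a consensus −10 17 bp downstream of a −35 gain F."""
        config, _ = small_dataset
        model = ActivityModel.from_config(config)
        rng = np.random.default_rng(3)
        background = "".join(rng.choice(list("ACGT"), 150))
        parent = background[:30] + "TTGACA" + background[36:]
        assert float(model.fluorescence(encode_many([parent]))[0]) < 1.1
        new10_start = 30 + 6 + 17
        gained = parent[:new10_start] + "TATAAT" + parent[new10_start + 6 :]
        daughters = [parent] * 200 + [gained] * 30
        F = model.fluorescence(encode_many(daughters))
        records = scan_associations(
            "P", parent, daughters, F, model.pwm10, [new10_start + 3]
        )
        at_box = [r for r in records if r.window_start == new10_start]
        assert at_box and at_box[0].direction == "gain"
        assert at_box[0].delta_F > 0.5

    def test_type_one_error_control_under_label_shuffle(self, small_dataset):
        """With shuffled labels the p<0.05 fraction stays near nominal."""
        model, parent, seqs, F, _ = self._planted(small_dataset)
        rng = np.random.default_rng(99)
        shuffled = rng.permutation(F)
        # permissive threshold so most windows have two usable groups
        results = list(
            association_tests(parent.sequence, seqs, shuffled, model.pwm10, threshold=-3.0)
        )
        assert len(results) > 50
        frac = np.mean([p < 0.05 for *_, p, _d in results])
        se = np.sqrt(0.05 * 0.95 / len(results))
        assert frac <= 0.05 + 3 * se

    def test_recovers_planted_gain_effect_size(self):
        """Recovered delta_F within ±0.15 of the planted effect."""
        from islandscan.synthetic_data import _bin_reads_many

        rng = np.random.default_rng(42)
        pwm = build_pwm(["TATAAT"])
        background = "".join(rng.choice(list("ACGT"), 60))
        assert "TATAAT" not in background
        carrier = background[:20] + "TATAAT" + background[26:]
        # latent values at bin centres so four-bin quantization is unbiased
        n, n_carriers = 600, 120
        latent = np.full(n, 1.0)
        latent[:n_carriers] = 3.0  # planted gain of +2.0 a.u.
        seqs = [carrier] * n_carriers + [background] * (n - n_carriers)
        counts = _bin_reads_many(latent, 50, 0.05, rng)
        F = (counts * np.arange(1, 5)).sum(axis=1) / counts.sum(axis=1)
        scores = pwm.score_positions(encode_many(seqs))[:, 20]
        p, delta = mwu_association(*window_partition(scores, F, pwm.threshold))
        assert p < 1e-6
        assert delta == pytest.approx(2.0, abs=0.15)


class TestNewBoxCensus:
    PWM = build_pwm(["TATAAT"])

    def test_daughters_identical_to_parent_empty(self):
        parent = "GGGGGGTATAATGGGGGG"
        assert new_box_census(parent, [parent] * 4, self.PWM) == set()

    def test_unique_new_positions_collected(self):
        parent = "G" * 100
        d1 = parent[:40] + "TATAAT" + parent[46:]
        d2 = parent[:40] + "TATAAT" + parent[46:90] + "TATAAT" + parent[96:]
        carriers = new_box_carriers(parent, [d1, d2], self.PWM)
        assert set(carriers) == {40, 90}
        assert carriers[40] == [0, 1] and carriers[90] == [1]

    def test_destroying_a_parent_box_is_not_a_gain(self):
        parent = "GGGGGGTATAATGGGGGG"
        broken = parent.replace("TATAAT", "TACGAT")
        assert new_box_census(parent, [broken], self.PWM) == set()


class TestClassifyGain:
    def _hit(self, cls, start):
        return MotifHit("p", "top", start, 6, 12.0, cls)

    def test_homo_gain(self):
        events = classify_gain(self._hit("minus10", 50), [self._hit("minus10", 49)])
        assert [e.gain_type for e in events] == ["homo"]

    def test_hetero_gain(self):
        events = classify_gain(self._hit("minus10", 50), [self._hit("minus35", 48)])
        assert [e.gain_type for e in events] == ["hetero"]

    def test_non_overlapping(self):
        events = classify_gain(self._hit("minus10", 10), [self._hit("minus10", 40)])
        assert [e.gain_type for e in events] == ["non_overlapping"]
        assert events[0].overlapped_parent_hit is None

    def test_both_classes_homo_first_both_reported(self):
        events = classify_gain(
            self._hit("minus10", 50),
            [self._hit("minus35", 48), self._hit("minus10", 52)],
        )
        assert [e.gain_type for e in events] == ["homo", "hetero"]


class TestSpacingAndTGnCensus:
    def test_spacer_and_tgn_counting(self):
        parent35 = [MotifHit("p", "top", 10, 6, 10.0, "minus35")]
        # new −10 at 33: spacer 17 from the parent −35; carrier has TG at 30..31
        daughter = "G" * 30 + "TGA" + "TATAAT" + "G" * 30
        new10 = {33: [0]}
        summary = census_spacing_and_tgn(new10, {}, [], parent35, [daughter])
        assert summary["n_new_boxes"] == 1
        assert summary["n_spaced"] == 1
        assert summary["n_tgn"] == 1

    def test_bad_spacer_not_counted(self):
        parent35 = [MotifHit("p", "top", 10, 6, 10.0, "minus35")]
        summary = census_spacing_and_tgn({41: [0]}, {}, [], parent35, ["G" * 80])
        assert summary["n_spaced"] == 0  # spacer 25

    def test_new_pair_counts_both_members(self):
        # new −35 at 0 and new −10 at 21: spacer 15 -> both spaced
        summary = census_spacing_and_tgn({21: [0]}, {0: [0]}, [], [], ["G" * 40])
        assert summary["n_new_boxes"] == 2
        assert summary["n_spaced"] == 2
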