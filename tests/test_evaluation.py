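import numpy as np
import pytest

from cgbvs import (
    ActivityRecord,
    DataError,
    auroc,
    build_dataset,
    enrichment_factor,
    label_screening_truth,
    make_half_sampled_split,
    make_virtual_orphan_split,
)
from cgbvs.evaluation import ACTIVE, INACTIVE
from cgbvs.io import NEGATIVE, POSITIVE, UNLABELED, Compound, Protein


def auroc_pair_counting_oracle(scores, labels):
    """Brute-force Mann-Whitney statistic with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def toy_dataset():
    comps = [Compound(f"c{i}", "CC") for i in range(6)]
    prots = [Protein(f"t{i}", "ACDEF") for i in range(1, 4)]
    recs = [
        ActivityRecord("c0", "t1", label=POSITIVE),
        ActivityRecord("c0", "t2", label=POSITIVE),
        ActivityRecord("c1", "t1", label=NEGATIVE),
        ActivityRecord("c2", "t2", label=POSITIVE),
        ActivityRecord("c3", "t3", label=POSITIVE),
        ActivityRecord("c4", "t1", label=UNLABELED),
    ]
    return build_dataset(comps, prots, recs)


class TestOrphanSplit:
    def test_train_excludes_orphan_records(self):
        ds = toy_dataset()
        split = make_virtual_orphan_split(ds, "t1")
        assert all(r.protein_id != "t1" for r in split.train.records)
        assert {r.protein_id for r in split.train.records} == {"t2", "t3"}
        # orphan protein itself stays available for protein features
        assert "t1" in split.train.proteins

    def test_shared_compound_keeps_other_target_record(self):
        split = make_virtual_orphan_split(toy_dataset(), "t1")
        assert any(r.compound_id == "c0" and r.protein_id == "t2"
                   for r in split.train.records)

    def test_zero_record_orphan_warns_all_inactive(self):
        ds = toy_dataset()
        comps = list(ds.compounds.values())
        prots = list(ds.proteins.values()) + [Protein("t9", "GHIKL")]
        ds2 = build_dataset(comps, prots, ds.records)
        with pytest.warns(UserWarning, match="no active"):
            split = make_virtual_orphan_split(ds2, "t9")
        assert set(split.test_truth.values()) == {INACTIVE}

    def test_unknown_target(self):
        with pytest.raises(DataError, match="unknown target"):
            make_virtual_orphan_split(toy_dataset(), "nope")

    def test_no_leakage_across_all_targets(self, small_fixture):
        for tid in small_fixture.dataset.proteins:
            split = make_virtual_orphan_split(small_fixture.dataset, tid)
            assert sum(r.protein_id == tid for r in split.train.records) == 0


class TestHalfSampledSplit:
    def _dataset(self, n_act=10, n_inact=10):
        comps = [Compound(f"c{i}", "CC") for i in range(n_act + n_inact)]
        prots = [Protein("t1", "ACDEF"), Protein("t2", "GHIKL")]
        recs = [ActivityRecord(f"c{i}", "t1",
                               label=POSITIVE if i < n_act else NEGATIVE)
                for i in range(n_act + n_inact)]
        recs.append(ActivityRecord("c0", "t2", label=POSITIVE))
        return build_dataset(comps, prots, recs)

    def test_stratified_halves(self):
        ds = self._dataset(10, 10)
        split = make_half_sampled_split(ds, "t1", seed=4)
        kept = [r for r in split.train.records if r.protein_id == "t1"]
        assert sum(r.label == POSITIVE for r in kept) == 5
        assert sum(r.label == NEGATIVE for r in kept) == 5
        assert len(split.excluded_compounds) == 10

    def test_same_seed_identical(self):
        ds = self._dataset()
        s1 = make_half_sampled_split(ds, "t1", seed=9)
        s2 = make_half_sampled_split(ds, "t1", seed=9)
        assert s1.test_truth == s2.test_truth
        assert {r.compound_id for r in s1.train.records} == \
               {r.compound_id for r in s2.train.records}

    def test_odd_count_rounding(self):
        ds = self._dataset(11, 0)
        split = make_half_sampled_split(ds, "t1", seed=0)
        kept = [r for r in split.train.records if r.protein_id == "t1"]
        assert len(kept) == 5  # floor(11/2) to train, 6 held out
        held_active = sum(v == ACTIVE for v in split.test_truth.values())
        assert held_active == 6

    def test_train_compounds_omitted_from_test(self):
        ds = self._dataset(10, 10)
        split = make_half_sampled_split(ds, "t1", seed=4)
        assert not (split.excluded_compounds & set(split.test_truth))


class TestScreeningTruth:
    def test_rules(self):
        ds = toy_dataset()
        truth, gap = label_screening_truth(ds, "t1", list(ds.compounds))
        assert truth["c0"] == ACTIVE       # positive record
        assert truth["c1"] == INACTIVE     # negative record
        assert truth["c5"] == INACTIVE     # no record at all
        assert truth["c4"] == INACTIVE and gap == {"c4"}  # gap potency, flagged

    def test_gap_exclusion_policy(self):
        ds = toy_dataset()
        truth, _ = label_screening_truth(ds, "t1", list(ds.compounds),
                                         gap_policy="exclude")
        assert "c4" not in truth

    def test_empty_library_error(self):
        with pytest.raises(DataError, match="empty"):
            label_screening_truth(toy_dataset(), "t1", [])


class TestEnrichmentFactor:
    def test_subset_size_floor(self):
        ids = [f"c{i}" for i in range(280648)]
        truth = {c: INACTIVE for c in ids}
        truth[ids[0]] = ACTIVE
        ef = enrichment_factor(ids, truth, fraction=0.01)
        assert ef.N_subset == 2806

    def test_direct_formula(self):
        ids = [f"c{i}" for i in range(1000)]
        actives = set(ids[:5]) | set(ids[500:545])  # 5 in top 10? build exact
        truth = {c: (ACTIVE if c in actives else INACTIVE) for c in ids}
        ef = enrichment_factor(ids, truth, fraction=0.01)
        assert ef.N_subset == 10 and ef.A_total == 50 and ef.A_found == 5
        assert ef.ef == pytest.approx(10.0)

    def test_maximum_attained(self):
        ids = [f"c{i}" for i in range(10000)]
        truth = {c: (ACTIVE if i < 50 else INACTIVE) for i, c in enumerate(ids)}
        ef = enrichment_factor(ids, truth, fraction=0.01)
        assert ef.N_subset == 100
        assert ef.ef == 100.0

    def test_minimum_subset_of_one(self):
        ids = ["a", "b", "c"]
        truth = {"a": ACTIVE, "b": INACTIVE, "c": INACTIVE}
        ef = enrichment_factor(ids, truth, fraction=0.01)
        assert ef.N_subset == 1 and ef.ef == pytest.approx(3.0)

    def test_no_actives_error(self):
        with pytest.raises(DataError, match="no active"):
            enrichment_factor(["a"], {"a": INACTIVE})

    def test_missing_truth_error(self):
        with pytest.raises(DataError, match="missing"):
            enrichment_factor(["a", "b"], {"a": ACTIVE})

    def test_random_ranking_mean_is_one(self, rng):
        # EF of a uniformly random ranking averages 1 (random screening)
        n, n_act, reps = 2000, 100, 300
        ids = np.arange(n)
        truth = {str(i): (ACTIVE if i < n_act else INACTIVE) for i in ids}
        efs = []
        for _ in range(reps):
            perm = rng.permutation(n)
            efs.append(enrichment_factor([str(i) for i in perm], truth).ef)
        efs = np.asarray(efs)
        se = efs.std(ddof=1) / np.sqrt(reps)
        assert abs(efs.mean() - 1.0) <= 3 * se

    def test_bounds(self, rng):
        n, n_act = 500, 40
        truth = {str(i): (ACTIVE if i < n_act else INACTIVE) for i in range(n)}
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(n)
            ef = enrichment_factor([str(i) for i in perm], truth)
            assert 0 <= ef.ef <= min(1 / 0.01, n / n_act)


class TestAUROC:
    def test_perfect_separation(self):
        r = auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auroc == 1.0

    def test_hand_counted(self):
        r = auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert r.auroc == pytest.approx(0.75)

    def test_all_ties(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auroc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = auroc(scores, labels).auroc
        assert got == pytest.approx(auroc_pair_counting_oracle(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        a = auroc(scores, labels).auroc
        b = auroc(np.exp(3 * scores) - 1, labels).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_endpoints_monotone(self, rng):
        r = auroc(rng.random(50), rng.integers(0, 2, 50) | np.arange(50) % 2)
        curve = r.curve
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0) and np.all(np.diff(curve[:, 1]) >= 0)

    def test_single_class_error(self):
        with pytest.raises(DataError, match="AUROC undefined"):
            auroc([0.1, 0.2], [1, 1])
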