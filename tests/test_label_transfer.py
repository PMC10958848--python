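import numpy as np
import pandas as pd
import pytest

from replicall import (
    CallAttributes,
    RegionSet,
    SplitSpec,
    assign_labels,
    build_candidates,
    consensus,
    detection_counts,
    evaluate_model,
    label_quality_experiment,
    split_by_chromosome,
    train_classifier,
)
from replicall.label_transfer import (
    LabelTransferError,
    candidate_keys,
    write_feature_table,
)

from conftest import attrs_for, make_callset, random_callset, vk


def caller_sets(*pos_lists):
    callers = ("mutect", "strelka", "ss")
    return [
        make_callset(p, caller=c, attrs=attrs_for([vk(x) for x in p]))
        for p, c in zip(pos_lists, callers)
    ]


@pytest.fixture
def regions():
    return RegionSet.from_intervals([("chr1", 0, 5000), ("chr2", 0, 5000)])


class TestBuildCandidates:
    def test_membership_flags(self):
        df = build_candidates(caller_sets([1], [1, 2], [1]),
                              negatives_per_positive=0)
        df = df.sort_values("POS").reset_index(drop=True)
        assert list(df["called_mutect"]) == [1, 0]
        assert list(df["called_strelka"]) == [1, 1]
        assert list(df["called_ss"]) == [1, 0]
        assert list(df["detection_count"]) == [3, 1]

    def test_zero_negatives_gives_exactly_the_union(self):
        sets = caller_sets([1, 5], [5, 9], [2])
        df = build_candidates(sets, negatives_per_positive=0)
        assert set(df["POS"]) == {1, 2, 5, 9}

    def test_negative_sampling_adds_uncalled_in_region_keys(self, regions):
        sets = caller_sets([1, 2, 3, 4], [1, 2], [3])
        df = build_candidates(sets, negatives_per_positive=1.0, seed=5,
                              regions=regions)
        union = {1, 2, 3, 4}
        neg = df[df["detection_count"] == 0]
        assert len(df) == 2 * len(union)
        assert len(neg) == len(union)
        assert not set(zip(neg["CHROM"], neg["POS"])) & {("chr1", p) for p in union}
        assert (neg[["called_mutect", "called_strelka", "called_ss"]] == 0).all().all()

    def test_negatives_require_regions(self):
        with pytest.raises(LabelTransferError, match="regions"):
            build_candidates(caller_sets([1], [1], [1]), negatives_per_positive=1.0)

    def test_flags_agree_with_detection_counts(self, rng):
        sets = [random_callset(rng, 40, universe=120, caller=c)
                for c in ("mutect", "strelka", "ss")]
        df = build_candidates(sets, negatives_per_positive=0)
        counts = detection_counts(sets, allow_mixed=True)
        for key, det in zip(candidate_keys(df), df["detection_count"]):
            assert counts[key] == det

    def test_missing_attributes_imputed_with_flag(self):
        cs = make_callset([7], caller="mutect")  # no attrs at all
        df = build_candidates([cs], negatives_per_positive=0)
        row = df.iloc[0]
        assert row["qual_mutect"] == 0.0 and row["qual_missing_mutect"] == 1
        assert row["vaf"] == 0.0 and row["vaf_missing"] == 1

    def test_empty_union_rejected(self):
        cs = make_callset([], caller="mutect")
        with pytest.raises(LabelTransferError, match="empty"):
            build_candidates([cs], negatives_per_positive=0)


class TestAssignLabels:
    def test_labels_equal_membership(self):
        df = build_candidates(caller_sets([1, 2], [2, 3], [4]),
                              negatives_per_positive=0)
        labeled = assign_labels(df, make_callset([2, 4, 99]), "truth")
        by_pos = dict(zip(labeled["POS"], labeled["label"]))
        assert by_pos == {1: 0, 2: 1, 3: 0, 4: 1}
        assert set(labeled["label_source"]) == {"truth"}

    def test_stricter_consensus_labels_are_subset(self, rng):
        reps = [random_callset(rng, 50, universe=100, replicate=i)
                for i in range(3)]
        candidates = build_candidates(
            [random_callset(rng, 60, universe=100, caller="mutect")],
            negatives_per_positive=0,
        )
        lab2 = assign_labels(candidates, consensus(reps, 2), "m2")
        lab3 = assign_labels(candidates, consensus(reps, 3), "m3")
        assert set(np.flatnonzero(lab3["label"])) <= set(np.flatnonzero(lab2["label"]))


class TestSplit:
    def make_labeled(self, chrom_pos):
        rows = []
        for chrom, pos in chrom_pos:
            rows.append({"CHROM": chrom, "POS": pos, "REF": "A", "ALT": "C",
                         "label": 0, "label_source": "t"})
        return pd.DataFrame(rows)

    def test_partition_is_disjoint_and_covering(self):
        df = self.make_labeled([("chr1", 1), ("chr5", 2), ("chr6", 3), ("chrX", 4)])
        spec = SplitSpec.first_n([f"chr{i}" for i in range(1, 23)], 5)
        train, test = split_by_chromosome(df, spec)
        assert set(train["CHROM"]) == {"chr1", "chr5"}
        assert set(test["CHROM"]) == {"chr6", "chrX"}
        assert len(train) + len(test) == len(df)

    def test_degenerate_split_raises_with_census(self):
        df = self.make_labeled([("chr1", 1), ("chr1", 2)])
        with pytest.raises(LabelTransferError, match="census"):
            split_by_chromosome(df, SplitSpec(frozenset({"chr1"})))

    def test_empty_train_chroms_rejected(self):
        df = self.make_labeled([("chr1", 1)])
        with pytest.raises(LabelTransferError):
            split_by_chromosome(df, SplitSpec(frozenset()))

    def test_random_chromosome_partition_property(self, rng):
        chroms = [f"chr{int(c)}" for c in rng.integers(1, 11, size=300)]
        df = self.make_labeled([(c, i + 1) for i, c in enumerate(chroms)])
        spec = SplitSpec(frozenset({"chr1", "chr3", "chr8"}))
        train, test = split_by_chromosome(df, spec)
        assert set(train["POS"]).isdisjoint(test["POS"])
        assert len(train) + len(test) == 300
        assert set(train["CHROM"]) <= spec.train_chroms
        assert set(test["CHROM"]).isdisjoint(spec.train_chroms)


def separable_training_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    for i in range(n):
        positive = i < half
        chrom = "chr1" if i % 2 else "chr7"
        rows.append({
            "CHROM": chrom, "POS": i + 1, "REF": "A", "ALT": "C",
            "called_mutect": int(positive), "qual_mutect": 40.0 * positive,
            "qual_missing_mutect": 0,
            "vaf": 0.5 * positive + 0.01 * rng.random(), "vaf_missing": 0,
            "tumor_depth": 50, "tumor_depth_missing": 0,
            "normal_depth": 50, "normal_depth_missing": 0,
            "detection_count": int(positive),
            "label": int(positive), "label_source": "truth",
        })
    df = pd.DataFrame(rows)
    df.attrs["caller_names"] = ["mutect"]
    return df


class TestClassifier:
    def test_separable_features_reach_training_accuracy_one(self):
        df = separable_training_frame()
        model = train_classifier(df, seed=0)
        pred = model.predict(df)
        assert (pred == df["label"].to_numpy(bool)).all()

    def test_same_seed_gives_identical_predictions(self):
        df = separable_training_frame()
        p1 = train_classifier(df, seed=3).estimator.predict_proba(
            df[train_classifier(df, seed=3).feature_names].to_numpy(float))
        p2 = train_classifier(df, seed=3).estimator.predict_proba(
            df[train_classifier(df, seed=3).feature_names].to_numpy(float))
        assert np.array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        df = separable_training_frame()
        df["label"] = 1
        with pytest.raises(LabelTransferError, match="single class"):
            train_classifier(df)

    def test_evaluation_is_against_truth_not_training_labels(self):
        df = separable_training_frame()
        train, test = split_by_chromosome(df, SplitSpec(frozenset({"chr1"})))
        model = train_classifier(train, seed=0)
        truth = make_callset(test.loc[test["label"] == 1, "POS"], chrom="chr7",
                             center="truth")
        t = evaluate_model(model, test, truth)
        assert t.f1 == pytest.approx(1.0)
        # against an empty truth set every positive prediction is an FP
        t0 = evaluate_model(model, test, make_callset([99999]))
        assert t0.precision < 0.2

    def test_always_positive_model_has_recall_one(self):
        df = separable_training_frame()
        train, test = split_by_chromosome(df, SplitSpec(frozenset({"chr1"})))
        model = train_classifier(train, seed=0, threshold=0.0)
        truth = make_callset(test["POS"], chrom="chr7", center="truth")
        assert evaluate_model(model, test, truth).recall == 1.0

    def test_feature_mismatch_raises(self):
        df = separable_training_frame()
        model = train_classifier(df, seed=0)
        with pytest.raises(LabelTransferError, match="missing"):
            model.predict(df.drop(columns=["vaf"]))

    def test_permuted_labels_destroy_test_performance(self):
        df = separable_training_frame(n=600, seed=2)
        train, test = split_by_chromosome(df, SplitSpec(frozenset({"chr1"})))
        truth = make_callset(test.loc[test["label"] == 1, "POS"], chrom="chr7",
                             center="truth")
        good = evaluate_model(train_classifier(train, seed=0), test, truth)
        rng = np.random.default_rng(0)
        shuffled = train.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        shuffled.attrs.update(train.attrs)
        null = evaluate_model(train_classifier(shuffled, seed=0), test, truth)
        assert null.f1 < good.f1 - 0.2


class TestLabelQualityExperiment:
    def test_table_shape_and_sources(self, small_bundle):
        table = label_quality_experiment(
            small_bundle, m_values=(1, 2, 3), seeds=(0,), center="AA",
            hyperparameters={"max_iter": 50},
        )
        assert len(table) == 4  # gt + three m rows
        assert set(table["label_source"]) == {
            "gt", "consensus_m>=1", "consensus_m>=2", "consensus_m>=3"}
        assert {"label_precision", "test_f1"} <= set(table.columns)

    def test_seeded_rerun_is_identical(self, small_bundle):
        kw = dict(m_values=(2,), seeds=(1,), center="AA",
                  hyperparameters={"max_iter": 50})
        t1 = label_quality_experiment(small_bundle, **kw)
        t2 = label_quality_experiment(small_bundle, **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_m_outside_replicate_count_rejected(self, small_bundle):
        with pytest.raises(LabelTransferError, match="outside"):
            label_quality_experiment(small_bundle, m_values=(5,), center="AA")

    def test_two_replicate_center_supported(self, small_bundle):
        table = label_quality_experiment(
            small_bundle, m_values=(1, 2), seeds=(0,), center="BB",
            hyperparameters={"max_iter": 50},
        )
        assert len(table) == 3

    def test_truth_labeled_model_beats_best_single_caller(self, small_bundle):
        # with noise-free labels the classifier should outperform each
        # caller's raw call set on the held-out chromosomes
        from replicall import ConfusionSummary, SplitSpec, confusion, metrics
        from replicall.label_transfer import candidate_keys

        table = label_quality_experiment(
            small_bundle, m_values=(1,), seeds=(0,), center="AA",
        )
        gt_f1 = table.loc[table["label_source"] == "gt", "test_f1"].iloc[0]
        cfg = small_bundle.config
        test_chroms = set(cfg.chroms[5:])
        best_caller = 0.0
        for caller in cfg.callers:
            cs = small_bundle.callsets[("AA", 1, "bwa", caller)]
            keys = {k for k in cs.keys if k.chrom in test_chroms}
            truth_keys = {k for k in small_bundle.truth.keys
                          if k.chrom in test_chroms}
            tp = len(keys & truth_keys)
            t = metrics(ConfusionSummary(tp, len(keys) - tp,
                                         len(truth_keys) - tp))
            best_caller = max(best_caller, t.f1)
        assert gt_f1 > best_caller


def test_feature_table_round_trip(tmp_path):
    df = build_candidates(caller_sets([1, 2], [2], [3]), negatives_per_positive=0)
    path = tmp_path / "features.tsv"
    write_feature_table(df, path)
    back = pd.read_csv(path, sep="\t")
    assert list(back.columns)[0] == "CHROM"
    assert len(back) == len(df)
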