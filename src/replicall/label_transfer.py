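"""Consensus-label training of a somatic variant classifier.

The experiment this module supports: build candidate variants from one
replicate's per-caller call sets, label them either with the validated
truth set or with a replicate-consensus set, train a gradient-boosted
tabular classifier on the first chromosomes and test on the rest, and ask
how close consensus-labeled models come to the truth-labeled model.

The classifier is a seeded gradient-boosted ensemble over caller-membership
flags and call attributes (quality, VAF, depths) — a deliberately
architecture-agnostic stand-in for heavier variant classifiers, since the
question under study is label quality, not architecture.  Candidates are
the union of caller calls plus (in simulation mode) sampled negative
positions; truth variants called by no caller are therefore out of reach
of any model, which mirrors candidate-driven classifiers generally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from .benchmark import ConfusionSummary, MetricTriple, confusion, metrics
from .consensus import consensus
from .variant_io import CallSet, RegionSet, VariantKey

KEY_COLUMNS = ["CHROM", "POS", "REF", "ALT"]


class LabelTransferError(ValueError):
    pass


def _feature_columns(caller_names: Sequence[str]) -> List[str]:
    cols = []
    for c in caller_names:
        cols += [f"called_{c}", f"qual_{c}", f"qual_missing_{c}"]
    cols += [
        "vaf", "vaf_missing",
        "tumor_depth", "tumor_depth_missing",
        "normal_depth", "normal_depth_missing",
        "detection_count",
    ]
    return cols


def _sample_negative_keys(
    regions: RegionSet,
    n: int,
    exclude: FrozenSet[VariantKey],
    rng: np.random.Generator,
) -> List[VariantKey]:
    """Uniform in-region positions carrying no call from any caller."""
    intervals = regions.intervals()
    lengths = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    total = int(lengths.sum())
    if total == 0:
        raise LabelTransferError("regions are empty; cannot sample negatives")
    cum = np.cumsum(lengths)
    bases = np.array(list("ACGT"))
    exclude_pos = {(k.chrom, k.pos) for k in exclude}
    out: List[VariantKey] = []
    seen = set()
    while len(out) < n:
        offs = rng.integers(0, total, size=max((n - len(out)) * 2, 16))
        refs = rng.integers(0, 4, size=offs.size)
        shifts = rng.integers(1, 4, size=offs.size)
        for i in range(offs.size):
            if len(out) >= n:
                break
            idx = int(np.searchsorted(cum, offs[i], side="right"))
            chrom, start, _ = intervals[idx]
            pos = int(start + offs[i] - (cum[idx] - lengths[idx]) + 1)
            if (chrom, pos) in exclude_pos or (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            ref = str(bases[refs[i]])
            alt = str(bases[(refs[i] + shifts[i]) % 4])
            out.append(VariantKey(chrom, pos, ref, alt))
    return out


def build_candidates(
    feature_callsets: Sequence[CallSet],
    negatives_per_positive: float = 1.0,
    seed: int = 0,
    regions: Optional[RegionSet] = None,
    negative_coverage: float = 100.0,
) -> pd.DataFrame:
    """Candidate table: union of caller calls plus sampled negatives.

    One row per candidate key with per-caller membership flags, per-caller
    quality, shared VAF/depth features (first caller carrying the key
    wins), missingness indicators, and the cross-caller detection count.
    Absent numeric values are imputed to 0 with the paired missingness flag
    set.  Negatives require ``regions``; ``negatives_per_positive=0``
    returns exactly the union.
    """
    if not feature_callsets:
        raise LabelTransferError("need at least one caller call set")
    caller_names = [cs.provenance.caller or f"caller{i}"
                    for i, cs in enumerate(feature_callsets)]
    if len(set(caller_names)) != len(caller_names):
        raise LabelTransferError(f"duplicate caller names: {caller_names}")
    union = frozenset().union(*(cs.keys for cs in feature_callsets))
    if not union:
        raise LabelTransferError("union of caller calls is empty")

    n_neg = int(round(negatives_per_positive * len(union)))
    negatives: List[VariantKey] = []
    if n_neg > 0:
        if regions is None:
            raise LabelTransferError("negative sampling requires regions")
        rng = np.random.default_rng(seed)
        negatives = _sample_negative_keys(regions, n_neg, union, rng)

    keys = sorted(union) + negatives
    rng_neg = np.random.default_rng(seed + 1)
    neg_depths = np.maximum(1, rng_neg.poisson(negative_coverage, size=len(negatives)))
    neg_ndepths = np.maximum(1, rng_neg.poisson(negative_coverage, size=len(negatives)))

    rows = []
    for i, key in enumerate(keys):
        row: Dict[str, object] = {
            "CHROM": key.chrom, "POS": key.pos, "REF": key.ref, "ALT": key.alt,
        }
        det = 0
        vaf = tdp = ndp = None
        for cs, name in zip(feature_callsets, caller_names):
            called = key in cs.keys
            det += called
            a = cs.attrs.get(key)
            qual = a.qual if (a is not None and a.qual is not None) else None
            row[f"called_{name}"] = int(called)
            row[f"qual_{name}"] = 0.0 if qual is None else float(qual)
            row[f"qual_missing_{name}"] = int(qual is None)
            if a is not None:
                vaf = a.vaf if vaf is None else vaf
                tdp = a.tumor_depth if tdp is None else tdp
                ndp = a.normal_depth if ndp is None else ndp
        is_negative = det == 0
        if is_negative:
            j = i - len(union)
            vaf, tdp, ndp = 0.0, int(neg_depths[j]), int(neg_ndepths[j])
        row["vaf"] = 0.0 if vaf is None else float(vaf)
        row["vaf_missing"] = int(vaf is None and not is_negative)
        row["tumor_depth"] = 0 if tdp is None else int(tdp)
        row["tumor_depth_missing"] = int(tdp is None and not is_negative)
        row["normal_depth"] = 0 if ndp is None else int(ndp)
        row["normal_depth_missing"] = int(ndp is None and not is_negative)
        row["detection_count"] = det
        rows.append(row)
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + _feature_columns(caller_names))
    df.attrs["caller_names"] = list(caller_names)
    return df


def candidate_keys(df: pd.DataFrame) -> List[VariantKey]:
    return [
        VariantKey(str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(df["CHROM"], df["POS"], df["REF"], df["ALT"])
    ]


def assign_labels(
    candidates: pd.DataFrame, label_set: CallSet, source: str
) -> pd.DataFrame:
    """Label each candidate 1 iff its key is in ``label_set``."""
    out = candidates.copy()
    keys = candidate_keys(candidates)
    out["label"] = [int(k in label_set.keys) for k in keys]
    out["label_source"] = source
    out.attrs.update(candidates.attrs)
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Chromosome-holdout split: train on ``train_chroms``, test on the
    complement within the data (or an explicit ``test_chroms``)."""

    train_chroms: FrozenSet[str]
    test_chroms: Optional[FrozenSet[str]] = None

    @classmethod
    def first_n(cls, chroms: Sequence[str], n: int = 5) -> "SplitSpec":
        return cls(train_chroms=frozenset(chroms[:n]))


def split_by_chromosome(
    labeled: pd.DataFrame, spec: SplitSpec
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition candidates by chromosome; train and test are disjoint and
    together cover the input."""
    if not spec.train_chroms:
        raise LabelTransferError("train_chroms is empty")
    chroms = set(labeled["CHROM"])
    if spec.test_chroms is not None and (spec.train_chroms & spec.test_chroms):
        raise LabelTransferError("train and test chromosome sets overlap")
    in_train = labeled["CHROM"].isin(spec.train_chroms)
    if spec.test_chroms is None:
        in_test = ~in_train
    else:
        in_test = labeled["CHROM"].isin(spec.test_chroms)
    train, test = labeled[in_train].copy(), labeled[in_test].copy()
    if len(train) == 0 or len(test) == 0:
        census = labeled["CHROM"].value_counts().to_dict()
        raise LabelTransferError(
            f"degenerate split (train={len(train)}, test={len(test)}); "
            f"chromosome census: {census}"
        )
    for part in (train, test):
        part.attrs.update(labeled.attrs)
    return train, test


@dataclass
class Model:
    """A trained classifier plus the feature order it expects."""

    estimator: HistGradientBoostingClassifier
    feature_names: List[str]
    threshold: float = 0.5
    metadata: Dict[str, object] = field(default_factory=dict)

    def predict(self, candidates: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in candidates.columns]
        if missing:
            raise LabelTransferError(f"feature columns missing: {missing}")
        proba = self.estimator.predict_proba(
            candidates[self.feature_names].to_numpy(dtype=float)
        )[:, 1]
        return proba >= self.threshold


def train_classifier(
    train: pd.DataFrame,
    hyperparameters: Optional[Mapping[str, object]] = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> Model:
    """Fit a seeded gradient-boosted classifier on the labeled candidates."""
    if "label" not in train.columns:
        raise LabelTransferError("training table has no 'label' column")
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise LabelTransferError("training labels contain a single class")
    caller_names = train.attrs.get("caller_names")
    if caller_names is None:  # infer from columns
        caller_names = [c[len("called_"):] for c in train.columns
                        if c.startswith("called_")]
    features = _feature_columns(caller_names)
    params: Dict[str, object] = {"max_iter": 200, "random_state": int(seed)}
    params.update(hyperparameters or {})
    est = HistGradientBoostingClassifier(**params)
    est.fit(train[features].to_numpy(dtype=float), y)
    return Model(
        estimator=est,
        feature_names=features,
        threshold=threshold,
        metadata={
            "seed": int(seed),
            "n_train": int(len(train)),
            "label_source": str(train["label_source"].iloc[0])
            if "label_source" in train.columns else "unknown",
        },
    )


def evaluate_model(model: Model, test: pd.DataFrame, truth: CallSet) -> MetricTriple:
    """Score predictions against truth membership of the test candidates.

    Evaluation is always against the truth set, never the training labels;
    FN counts truth candidates the model rejected (truth variants that are
    not candidates cannot be scored).
    """
    if len(test) == 0:
        raise LabelTransferError("test set is empty")
    pred = model.predict(test)
    keys = candidate_keys(test)
    actual = np.array([k in truth.keys for k in keys])
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    fn = int(np.sum(~pred & actual))
    return metrics(ConfusionSummary(tp=tp, fp=fp, fn=fn))


def _label_set_quality(labeled: pd.DataFrame, truth: CallSet) -> Tuple[float, float]:
    """Precision/recall of the training labels themselves against truth,
    computed over the labeled candidates."""
    keys = candidate_keys(labeled)
    lab = labeled["label"].to_numpy(dtype=bool)
    actual = np.array([k in truth.keys for k in keys])
    tp = int(np.sum(lab & actual))
    fp = int(np.sum(lab & ~actual))
    fn = int(np.sum(~lab & actual))
    t = metrics(ConfusionSummary(tp=tp, fp=fp, fn=fn))
    return t.precision, t.recall


def label_quality_experiment(
    bundle,
    m_values: Sequence[int] = (1, 2, 3),
    seeds: Sequence[int] = (0,),
    center: Optional[str] = None,
    feature_mapper: str = "bwa",
    label_pipeline: Tuple[str, str] = ("bwa", "mutect"),
    negatives_per_positive: float = 1.0,
    train_chroms: Optional[FrozenSet[str]] = None,
    hyperparameters: Optional[Mapping[str, object]] = None,
) -> pd.DataFrame:
    """Compare consensus-labeled models against the truth-labeled model.

    Candidates and features come from the first replicate of ``center``
    (one call set per caller under ``feature_mapper``).  Label sets are the
    within-center consensus of ``label_pipeline`` at each m, plus a
    ground-truth row per seed.  Every model is evaluated on the held-out
    chromosomes against the truth set.
    """
    cfg = bundle.config
    if center is None:
        center = next(p.name for p in cfg.centers if p.n_replicates >= 2)
    profile = next(p for p in cfg.centers if p.name == center)
    n_reps = profile.n_replicates
    if n_reps < 2:
        raise LabelTransferError(f"center {center} has {n_reps} replicate(s)")
    bad = [m for m in m_values if not 1 <= m <= n_reps]
    if bad:
        raise LabelTransferError(f"m values {bad} outside 1..{n_reps}")

    caller_names = list(cfg.callers)
    feature_callsets = [
        bundle.callsets[(center, 1, feature_mapper, c)] for c in caller_names
    ]
    candidates = build_candidates(
        feature_callsets,
        negatives_per_positive=negatives_per_positive,
        seed=cfg.seed,
        regions=bundle.regions,
    )
    if train_chroms is None:
        spec = SplitSpec.first_n(list(cfg.chroms), 5)
    else:
        spec = SplitSpec(train_chroms=frozenset(train_chroms))

    mapper, caller = label_pipeline
    label_replicates = [
        bundle.callsets[(center, r, mapper, caller)] for r in range(1, n_reps + 1)
    ]

    label_sets = [("gt", None, bundle.truth)]
    for m in m_values:
        cons = consensus(label_replicates, m, group_label=f"{center}_m{m}")
        label_sets.append((f"consensus_m>={m}", m, cons))

    rows = []
    for source, m, label_set in label_sets:
        labeled = assign_labels(candidates, label_set, source)
        train, test = split_by_chromosome(labeled, spec)
        lp, lr = _label_set_quality(labeled, bundle.truth)
        for seed in seeds:
            model = train_classifier(train, hyperparameters=hyperparameters,
                                     seed=seed)
            t = evaluate_model(model, test, bundle.truth)
            rows.append(
                {
                    "label_source": source,
                    "m": 0 if m is None else m,
                    "seed": seed,
                    "label_precision": lp,
                    "label_recall": lr,
                    "test_precision": t.precision,
                    "test_recall": t.recall,
                    "test_f1": t.f1,
                }
            )
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """TSV with CHROM as the first column (ensemble-feature convention)."""
    cols = KEY_COLUMNS + [c for c in df.columns if c not in KEY_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)
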