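"""The evaluation battery: person sampling, cross-week / cross-task /
cross-twin / cross-channel / regional identification, label-permutation
chance calibration, and weight-spectrum extraction.

All multi-repetition protocols follow the same convention: 10 subjects are
drawn per repetition either one-per-pair ("nontwin") or as whole twin pairs
("twin"), the classifier is trained on weeks 1-3 and tested on week 4
(unless the protocol says otherwise), and the reported number is the mean
final-vote accuracy with its standard error over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify
from .classify import VotingScheme
from .features import FeatureSet
from .montage import DEFAULT_REGIONS


@dataclass(frozen=True)
class PersonSample:
    """One repetition's subject draw."""

    mode: str  # "nontwin" | "twin"
    subjects: tuple[int, ...]
    repetition: int
    seed: int


def sample_persons(
    n_pairs: int, mode: str, n_reps: int = 20, seed: int = 0
) -> list[PersonSample]:
    """Draw ``n_reps`` independent 10-person samples.

    "nontwin": one subject from each pair (no two share a pair);
    "twin": half the pairs, both siblings included.
    """
    if mode not in ("nontwin", "twin"):
        raise ValueError("mode must be 'nontwin' or 'twin'")
    samples = []
    for rep in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        )
        if mode == "nontwin":
            picks = tuple(
                2 * p - 1 + int(rng.integers(0, 2)) for p in range(1, n_pairs + 1)
            )
        else:
            pairs = 1 + rng.choice(n_pairs, size=n_pairs // 2, replace=False)
            picks = tuple(
                s for p in sorted(pairs) for s in (2 * p - 1, 2 * p)
            )
        samples.append(PersonSample(mode, picks, rep, seed))
    return samples


@dataclass
class ExperimentResult:
    """Accuracies per repetition with their mean and standard error."""

    name: str
    per_rep: pd.DataFrame  # index: repetition; columns: protocol cells
    confusion: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_rep.mean(axis=0)

    @property
    def se(self) -> pd.Series:
        n = len(self.per_rep)
        return self.per_rep.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
            self.per_rep.iloc[0] * 0.0


def evaluate_split(
    features: FeatureSet,
    subjects,
    train_weeks,
    test_weeks,
    train_tasks=None,
    test_tasks=None,
    C: float = 1.0,
    voting: VotingScheme | None = None,
    train_mask=None,
    test_mask=None,
) -> dict:
    """Train on one slice of the FeatureSet, vote-test on another."""
    train = features.subset(subjects=subjects, weeks=train_weeks,
                            tasks=train_tasks, mask=train_mask)
    test = features.subset(subjects=subjects, weeks=test_weeks,
                           tasks=test_tasks, mask=test_mask)
    model = classify.fit(train, C=C)
    raw = classify.predict_raw(model, test)
    final = classify.vote(raw, voting or VotingScheme())
    return {
        "model": model,
        "raw": raw,
        "final": final,
        "raw_accuracy": classify.accuracy(raw),
        "final_accuracy": classify.accuracy(final),
    }


def run_single_day(
    features: FeatureSet,
    samples: list[PersonSample],
    week: int = 1,
    tasks=("mbi", "mbe"),
    train_fraction: float = 2 / 3,
    C: float = 1.0,
    voting: VotingScheme | None = None,
) -> ExperimentResult:
    """Within-session identification: early segments train, late test."""
    seg = features.meta["segment"].to_numpy()
    n_seg = int(seg.max()) + 1
    cutoff = int(n_seg * train_fraction)
    rows = []
    for s in samples:
        res = evaluate_split(
            features, s.subjects, [week], [week], tasks, tasks, C, voting,
            train_mask=seg < cutoff, test_mask=seg >= cutoff,
        )
        rows.append({"accuracy": res["final_accuracy"]})
    return ExperimentResult("single_day", pd.DataFrame(rows),
                            extra={"week": week, "cutoff": cutoff})


def run_cross_week(
    features: FeatureSet,
    samples: list[PersonSample],
    train_week: int = 1,
    test_weeks=(2, 3, 4),
    tasks=("mbi", "mbe"),
    C: float = 1.0,
    voting: VotingScheme | None = None,
) -> ExperimentResult:
    """Train on one week, test on later weeks: temporal stability curve."""
    rows = []
    for s in samples:
        train = features.subset(subjects=s.subjects, weeks=[train_week], tasks=tasks)
        model = classify.fit(train, C=C)
        row = {}
        for tw in test_weeks:
            test = features.subset(subjects=s.subjects, weeks=[tw], tasks=tasks)
            final = classify.vote(classify.predict_raw(model, test),
                                  voting or VotingScheme())
            row[tw] = classify.accuracy(final)
        rows.append(row)
    return ExperimentResult(
        "cross_week", pd.DataFrame(rows),
        extra={"train_week": train_week, "tasks": list(tasks)},
    )


def run_multiweek(
    features: FeatureSet,
    samples: list[PersonSample],
    train_weeks=(1, 2, 3),
    test_week: int = 4,
    tasks=None,
    C: float = 1.0,
    voting: VotingScheme | None = None,
) -> ExperimentResult:
    """The headline protocol: weeks 1-3 train, week 4 vote-test."""
    rows = []
    for s in samples:
        res = evaluate_split(
            features, s.subjects, train_weeks, [test_week], tasks, tasks, C, voting
        )
        rows.append({"raw": res["raw_accuracy"], "final": res["final_accuracy"]})
    return ExperimentResult(
        "multiweek", pd.DataFrame(rows),
        extra={"train_weeks": list(train_weeks), "test_week": test_week},
    )


def run_cross_task(
    features: FeatureSet,
    samples: list[PersonSample],
    tasks=None,
    train_weeks=(1, 2, 3),
    test_week: int = 4,
    C: float = 1.0,
    voting: VotingScheme | None = None,
) -> ExperimentResult:
    """Task x task transfer matrix: train on one task's weeks 1-3, test on
    every task's week 4. Cells are mean final accuracies over repetitions."""
    tasks = list(tasks) if tasks is not None else sorted(features.meta["task"].unique())
    acc = np.zeros((len(samples), len(tasks), len(tasks)))
    for ri, s in enumerate(samples):
        for ti, train_task in enumerate(tasks):
            train = features.subset(subjects=s.subjects, weeks=train_weeks,
                                    tasks=[train_task])
            model = classify.fit(train, C=C)
            for tj, test_task in enumerate(tasks):
                test = features.subset(subjects=s.subjects, weeks=[test_week],
                                       tasks=[test_task])
                final = classify.vote(classify.predict_raw(model, test),
                                      voting or VotingScheme())
                acc[ri, ti, tj] = classify.accuracy(final)
    cols = pd.MultiIndex.from_product([tasks, tasks], names=["train", "test"])
    per_rep = pd.DataFrame(acc.reshape(len(samples), -1), columns=cols)
    matrix = pd.DataFrame(acc.mean(axis=0), index=tasks, columns=tasks)
    return ExperimentResult("cross_task", per_rep, extra={"matrix": matrix})


def run_confusion(
    features: FeatureSet,
    subjects=None,
    train_weeks=(1, 2, 3),
    test_week: int = 4,
    tasks=None,
    C: float = 1.0,
    voting: VotingScheme | None = None,
    level: str = "final",
) -> ExperimentResult:
    """Whole-cohort identification with a row-normalized confusion matrix.

    ``level`` selects whether the matrix tabulates final votes (default) or
    raw per-segment predictions; raw predictions give the finer-grained
    (and, per row, far larger) sample of the classifier's confusion
    structure.
    """
    subjects = list(subjects) if subjects is not None else features.subjects
    res = evaluate_split(features, subjects, train_weeks, [test_week],
                         tasks, tasks, C, voting)
    pred = res[level if level in ("raw", "final") else "final"]
    conf = classify.confusion(pred, labels=np.array(subjects))
    acc = classify.accuracy(pred)
    per_rep = pd.DataFrame([{"accuracy": acc, "raw": res["raw_accuracy"],
                             "final": res["final_accuracy"]}])
    return ExperimentResult("confusion", per_rep, confusion=conf,
                            extra={"level": level, "n_subjects": len(subjects)})


def run_regional(
    features: FeatureSet,
    samples_by_mode: dict[str, list[PersonSample]],
    region_map: dict[str, tuple[str, ...]] | None = None,
    tasks=("rce", "roe", "mbi", "ibi"),
    train_weeks=(1, 2, 3),
    test_week: int = 4,
    C: float = 1.0,
    voting: VotingScheme | None = None,
) -> ExperimentResult:
    """Identification from single scalp regions, per task and sampling mode.

    Returns per-repetition accuracies for every (mode, task, region) cell;
    ``extra['table']`` holds the mean +/- se summary table.
    """
    region_map = region_map or DEFAULT_REGIONS
    for name, chans in region_map.items():
        if not chans:
            raise ValueError(f"region {name!r} is empty")
    regional = {name: features.select_channels(chans)
                for name, chans in region_map.items()}
    rows = []
    for mode, samples in samples_by_mode.items():
        for s in samples:
            for task in tasks:
                for region, feats in regional.items():
                    res = evaluate_split(feats, s.subjects, train_weeks,
                                         [test_week], [task], [task], C, voting)
                    rows.append({
                        "mode": mode, "repetition": s.repetition, "task": task,
                        "region": region, "accuracy": res["final_accuracy"],
                    })
    per_rep = pd.DataFrame(rows)
    table = (
        per_rep.groupby(["mode", "task", "region"])["accuracy"]
        .agg(["mean", "sem"])
        .unstack("region")
    )
    return ExperimentResult("regional", per_rep, extra={"table": table})


def run_label_permutation(
    features: FeatureSet,
    samples: list[PersonSample],
    tasks=None,
    train_weeks=(1, 2, 3),
    test_week: int = 4,
    C: float = 1.0,
    voting: VotingScheme | None = None,
    seed: int = 0,
    unit: str = "segment",
) -> ExperimentResult:
    """Chance calibration: retrain after permuting training identities.

    Training labels are shuffled across segments (``unit="segment"``, the
    exchangeability null: the fitted model carries no identity information
    at all) or across whole recordings (``unit="recording"``); test
    accuracy should sit at the 1/n_subjects chance level.
    """
    rows = []
    n_votes = 0
    for s in samples:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1000 + s.repetition,))
        )
        train = features.subset(subjects=s.subjects, weeks=train_weeks, tasks=tasks)
        shuffled = train.subset()  # copy
        shuffled.meta = shuffled.meta.copy()
        if unit == "segment":
            shuffled.meta["subject"] = rng.permutation(
                train.meta["subject"].to_numpy()
            )
        elif unit == "recording":
            groups = train.meta.groupby(
                list(train.group_cols), sort=True
            ).ngroup().to_numpy()
            uniq = np.unique(groups)
            group_labels = train.meta.groupby(
                list(train.group_cols), sort=True
            )["subject"].first().to_numpy()
            permuted = rng.permutation(group_labels)
            shuffled.meta["subject"] = permuted[np.searchsorted(uniq, groups)]
        else:
            raise ValueError("unit must be 'segment' or 'recording'")
        model = classify.fit(shuffled, C=C)
        test = features.subset(subjects=s.subjects, weeks=[test_week], tasks=tasks)
        final = classify.vote(classify.predict_raw(model, test),
                              voting or VotingScheme())
        rows.append({"accuracy": classify.accuracy(final)})
        n_votes += len(final)
    return ExperimentResult("label_permutation", pd.DataFrame(rows),
                            extra={"n_votes": n_votes})


# --------------------------------------------------------------------------
# weight-spectrum inspection and confusion summaries


def extract_base_signal_weights(model: classify.IdentityModel) -> dict:
    """Reshape each subject's weight vector into plot-ready spectra.

    Concatenated-mode models yield one (n_channels, n_bins) array per
    subject; channel-wise models one (n_bins,) spectrum. Returns
    ``{"freqs": bin frequencies, "channels": ..., "weights": {subject: arr}}``.
    """
    if model.mode == "channelwise" or model.feature_channels is None:
        return {
            "freqs": model.feature_freqs,
            "channels": None,
            "weights": {int(lab): w for lab, w in zip(model.labels, model.coef)},
        }
    channels = list(dict.fromkeys(model.feature_channels))
    n_bins = model.n_features // len(channels)
    if n_bins * len(channels) != model.n_features or not np.array_equal(
        np.asarray(model.feature_channels), np.repeat(channels, n_bins)
    ):
        raise ValueError("feature layout does not factor into channels x bins")
    return {
        "freqs": model.feature_freqs[:n_bins],
        "channels": channels,
        "weights": {
            int(lab): w.reshape(len(channels), n_bins)
            for lab, w in zip(model.labels, model.coef)
        },
    }


def complementary_nontwin_weights(
    features: FeatureSet,
    sample: PersonSample,
    train_weeks=(1, 2, 3),
    tasks=None,
    C: float = 1.0,
) -> dict[int, np.ndarray]:
    """Weight spectra for all subjects from two sibling-free models.

    One-vs-all discriminators trained with both siblings present are forced
    to *separate* the pair, anti-aligning their weights; the base-signal
    similarity of twins shows in models where each sibling is discriminated
    only against unrelated people. A non-twin sample and its complement
    (the left-out sibling of every pair) provide exactly that: every
    subject appears in one of the two models and siblings never co-occur.
    """
    if sample.mode != "nontwin":
        raise ValueError("needs a nontwin sample")
    all_subjects = set(features.subjects)
    complement = tuple(sorted(all_subjects - set(sample.subjects)))
    weights: dict[int, np.ndarray] = {}
    for subjects in (sample.subjects, complement):
        train = features.subset(subjects=subjects, weeks=train_weeks, tasks=tasks)
        model = classify.fit(train, C=C)
        weights.update(
            {int(lab): w for lab, w in zip(model.labels, model.coef)}
        )
    return weights


def weight_similarity(weights: dict[int, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation between subjects' flattened weight spectra."""
    subjects = sorted(weights)
    flat = np.vstack([weights[s].ravel() for s in subjects])
    return pd.DataFrame(np.corrcoef(flat), index=subjects, columns=subjects)


def sibling_vs_nonsibling_correlation(sim: pd.DataFrame) -> tuple[float, float]:
    """Mean within-pair vs between-pair off-diagonal correlation."""
    subs = list(sim.index)
    within, between = [], []
    for i, a in enumerate(subs):
        for b in subs[i + 1:]:
            (within if (a + 1) // 2 == (b + 1) // 2 else between).append(sim.loc[a, b])
    return float(np.mean(within)), float(np.mean(between))


def within_between_pair_confusion(conf: pd.DataFrame) -> tuple[float, float]:
    """Mean off-diagonal confusion mass within vs between twin pairs."""
    within, between = [], []
    for a in conf.index:
        for b in conf.columns:
            if a == b:
                continue
            (within if (a + 1) // 2 == (b + 1) // 2 else between).append(conf.loc[a, b])
    return float(np.mean(within)), float(np.mean(between))


def pair_mass_split(conf: pd.DataFrame) -> pd.DataFrame:
    """Per twin pair: row-normalized mass on self vs sibling.

    Averages the pair's two rows; columns ``diagonal`` and ``sibling``
    should approach 50/50 when siblings are indistinguishable.
    """
    rows = []
    subs = sorted(conf.index)
    for p in range(1, len(subs) // 2 + 1):
        a, b = 2 * p - 1, 2 * p
        diag = (conf.loc[a, a] + conf.loc[b, b]) / 2
        sib = (conf.loc[a, b] + conf.loc[b, a]) / 2
        rows.append({"pair": p, "diagonal": diag, "sibling": sib})
    return pd.DataFrame(rows).set_index("pair")
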