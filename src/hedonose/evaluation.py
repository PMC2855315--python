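"""Evaluation battery: leave-group-out CV, exclusion-band classification,
permutation null, power analysis, and human-agreement statistics.

All train/test splits group by odorant — every repetition of a held-out
odorant leaves the training set together, so repeated measurements of one
odorant can never leak across the split.  Correlation p-values are the
conventional two-tailed t-transform with n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    PleasantnessTable,
    RatingTable,
    VAS_MID,
    as_pleasantness_table,
)
from .features import FeatureMatrix
from .model import NetworkSpec, PleasantnessModel

ALPHA = 0.05


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class CVResult:
    """Per-repeat correlations of a leave-group-out cross-validation."""

    r_values: np.ndarray
    p_values: np.ndarray
    group_size: int

    @property
    def median_r(self) -> float:
        return float(np.median(self.r_values))

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.p_values))

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < ALPHA))

    def to_dict(self) -> dict:
        return {
            "group_size": self.group_size,
            "median_r": self.median_r,
            "mean_r": self.mean_r,
            "mean_p": self.mean_p,
            "median_p": self.median_p,
            "fraction_p_below_0.05": self.fraction_significant,
            "r_values": self.r_values.tolist(),
            "p_values": self.p_values.tolist(),
        }


def _fit_and_score(
    features: FeatureMatrix,
    table: PleasantnessTable,
    train_odorants: Sequence[str],
    test_odorants: Sequence[str],
    spec: NetworkSpec,
    seed: int,
) -> tuple[float, float]:
    """Train on one odorant subset, return (r, p) on the held-out odorants."""
    train = features.rows_for_odorants(train_odorants)
    test = features.rows_for_odorants(test_odorants)
    model = PleasantnessModel(train, table, spec=spec)
    res = model.fit(seed=seed)
    _, pred = res.predict(test)
    truth = np.array([table[o] - VAS_MID for o in pred.index])
    r, p = stats.pearsonr(pred.values, truth)
    return float(r), float(p)


def leave_group_out(
    features: FeatureMatrix,
    targets,
    group_size: int,
    n_repeats: int = 20,
    seed: int = 0,
    spec: NetworkSpec | None = None,
) -> CVResult:
    """Repeatedly hold out a random group of odorants, train on the rest,
    and correlate predicted with observed median pleasantness.

    ``group_size`` counts odorants, not measurements; groups below 3 make
    the correlation degenerate and are rejected.
    """
    spec = spec or NetworkSpec()
    table = as_pleasantness_table(targets)
    odorants = list(dict.fromkeys(features.odorant_ids))
    if group_size < 3:
        raise ValueError("group_size must be >= 3 for a meaningful correlation")
    if group_size >= len(odorants):
        raise ValueError("group_size must be smaller than the number of odorants")
    rng = np.random.default_rng(seed)
    seeds = _spawn_seeds(seed, n_repeats)
    rs, ps = [], []
    for rep in range(n_repeats):
        held = list(rng.choice(odorants, size=group_size, replace=False))
        train = [o for o in odorants if o not in set(held)]
        r, p = _fit_and_score(features, table, train, held, spec, seeds[rep])
        rs.append(r)
        ps.append(p)
    return CVResult(np.array(rs), np.array(ps), group_size)


@dataclass(frozen=True)
class ExclusionBand:
    """Mid-scale VAS interval (low, high) excluded from classification scoring."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low <= self.high <= 30:
            raise ValueError("need 0 <= low <= high <= 30")

    def excludes(self, vas: np.ndarray) -> np.ndarray:
        return (vas > self.low) & (vas < self.high)

    @property
    def label(self) -> str:
        return "none" if self.low == self.high else f"{self.low:g}-{self.high:g}"


#: the symmetric band grid (15-k, 15+k), k = 0..5, from none through 10-20
DEFAULT_BANDS: tuple[ExclusionBand, ...] = tuple(
    ExclusionBand(VAS_MID - k, VAS_MID + k) for k in range(6)
)


def classification_accuracy(
    predictions: pd.Series,
    median_vas: pd.Series,
    band: ExclusionBand = DEFAULT_BANDS[0],
    sample_predictions: pd.Series | None = None,
    sample_odorants: Mapping[str, str] | None = None,
) -> dict:
    """Sign-classification accuracy outside an exclusion band.

    ``predictions`` are centered per-odorant predictions; an odorant counts
    as correctly classified when sign(prediction) matches
    sign(median VAS - 15).  Odorants with median VAS strictly inside the
    band are excluded from scoring.  If per-sample predictions are supplied,
    a secondary per-measurement accuracy over the same odorants is emitted.
    """
    common = [o for o in predictions.index if o in median_vas.index]
    vas = median_vas.loc[common].to_numpy(dtype=float)
    keep = ~band.excludes(vas)
    if not keep.any():
        raise ValueError(f"all odorants fall inside the exclusion band {band.label}")
    kept = [o for o, k in zip(common, keep) if k]
    pred_pleasant = predictions.loc[kept].to_numpy() > 0
    true_pleasant = median_vas.loc[kept].to_numpy(dtype=float) - VAS_MID > 0
    out = {
        "band": band.label,
        "n_scored": len(kept),
        "n_excluded": len(common) - len(kept),
        "accuracy": float(np.mean(pred_pleasant == true_pleasant)),
    }
    if sample_predictions is not None and sample_odorants is not None:
        rows = [
            (sample_predictions[s] > 0,
             float(median_vas[sample_odorants[s]]) - VAS_MID > 0)
            for s in sample_predictions.index
            if sample_odorants[s] in set(kept)
        ]
        if rows:
            p_arr, t_arr = map(np.array, zip(*rows))
            out["per_measurement_accuracy"] = float(np.mean(p_arr == t_arr))
            out["n_measurements_scored"] = len(rows)
    return out


def exclusion_sweep(
    predictions: pd.Series,
    median_vas: pd.Series,
    bands: Sequence[ExclusionBand] = DEFAULT_BANDS,
    **kwargs,
) -> list[dict]:
    """Classification accuracy across a grid of widening exclusion bands."""
    return [
        classification_accuracy(predictions, median_vas, band, **kwargs)
        for band in bands
    ]


@dataclass
class PermutationResult:
    """Null distribution from label-scrambled retraining."""

    r_values: np.ndarray
    p_values: np.ndarray

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.p_values))

    def to_dict(self) -> dict:
        return {
            "n_perm": len(self.r_values),
            "mean_r": self.mean_r,
            "mean_p": self.mean_p,
            "r_values": self.r_values.tolist(),
        }


def permutation_control(
    features: FeatureMatrix,
    targets,
    n_perm: int = 100,
    seed: int = 0,
    group_size: int = 25,
    spec: NetworkSpec | None = None,
) -> PermutationResult:
    """Scramble the odorant-to-pleasantness assignment ``n_perm`` times and
    rerun the standard train/test protocol each time.

    Each permutation shuffles which odorant carries which median rating,
    retrains the full ensemble on a random training set, and records the
    held-out correlation (held-out group of ``group_size`` odorants).  The
    mean r over permutations calibrates the null of the whole pipeline.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    spec = spec or NetworkSpec()
    table = as_pleasantness_table(targets)
    odorants = list(dict.fromkeys(features.odorant_ids))
    values = np.array([table[o] for o in odorants])
    rng = np.random.default_rng(seed)
    seeds = _spawn_seeds(seed, n_perm)
    rs, ps = [], []
    for k in range(n_perm):
        shuffled = values[rng.permutation(len(values))]
        scrambled = as_pleasantness_table(pd.Series(shuffled, index=odorants))
        held = list(rng.choice(odorants, size=group_size, replace=False))
        train = [o for o in odorants if o not in set(held)]
        r, p = _fit_and_score(features, scrambled, train, held, spec, seeds[k])
        rs.append(r)
        ps.append(p)
    return PermutationResult(np.array(rs), np.array(ps))


def power_curve(
    features: FeatureMatrix,
    targets,
    training_sizes: Sequence[int],
    n_repeats: int = 20,
    seed: int = 0,
    test_size: int = 20,
    spec: NetworkSpec | None = None,
) -> pd.DataFrame:
    """Prediction quality versus training-set size.

    A fixed held-out test set of ``test_size`` odorants is drawn once; for
    each training size, ``n_repeats`` random subsets of the remaining
    odorants are used to train, and the held-out correlation is aggregated
    into mean r, the fraction of non-significant repeats (p > 0.05) and the
    mean p per size.
    """
    spec = spec or NetworkSpec()
    table = as_pleasantness_table(targets)
    odorants = list(dict.fromkeys(features.odorant_ids))
    if max(training_sizes) > len(odorants) - test_size:
        raise ValueError("largest training size exceeds available odorants")
    rng = np.random.default_rng(seed)
    test = list(rng.choice(odorants, size=test_size, replace=False))
    pool = [o for o in odorants if o not in set(test)]
    rows = []
    for size in training_sizes:
        seeds = _spawn_seeds(seed + size, n_repeats)
        rs, ps = [], []
        for rep in range(n_repeats):
            train = list(rng.choice(pool, size=size, replace=False))
            r, p = _fit_and_score(features, table, train, test, spec, seeds[rep])
            rs.append(r)
            ps.append(p)
        rows.append(
            {
                "training_size": size,
                "mean_r": float(np.mean(rs)),
                "fraction_p_above_0.05": float(np.mean(np.array(ps) > ALPHA)),
                "mean_p": float(np.mean(ps)),
            }
        )
    return pd.DataFrame(rows)


def machine_human_percent(
    machine_r: float, human_r: float, mode: str = "trunc"
) -> int:
    """Machine-to-human agreement as an integer percent of 100*machine/human.

    ``trunc`` (default) truncates toward zero; ``nearest`` rounds half to
    even.  Both conventions appear in published agreement arithmetic, so the
    choice is explicit.
    """
    pct = 100.0 * machine_r / human_r
    if mode == "trunc":
        return int(pct)
    if mode == "nearest":
        return int(round(pct))
    raise ValueError(f"unknown rounding mode {mode!r}")


@dataclass
class AgreementReport:
    """Human-agreement statistics and the machine-to-human ratio.

    Three distinct human-to-human quantities are reported and named
    explicitly because they are easily conflated: the mean pairwise
    subject-subject correlation, the mean subject-to-group-median
    correlation, and the mean within-subject test-retest correlation.
    """

    pairwise_human_r: float
    human_to_median_r: float
    test_retest_r: float
    machine_human_r: float
    machine_human_p: float
    percent_of_human: int
    n_subjects: int
    n_pairs: int
    rounding: str = "trunc"
    per_subject_to_median: pd.Series = field(default_factory=pd.Series, repr=False)

    def to_dict(self) -> dict:
        return {
            "pairwise_human_r": self.pairwise_human_r,
            "human_to_median_r": self.human_to_median_r,
            "test_retest_r": self.test_retest_r,
            "machine_human_r": self.machine_human_r,
            "machine_human_p": self.machine_human_p,
            "percent_of_human": self.percent_of_human,
            "n_subjects": self.n_subjects,
            "n_pairs": self.n_pairs,
        }


def _subject_vectors(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-subject odorant vectors: mean over that subject's sessions."""
    return frame.groupby(["subject", "odorant"])["vas"].mean().unstack("odorant")


def agreement_stats(
    ratings: RatingTable,
    machine_pred: pd.Series,
    min_common: int = 3,
    rounding: str = "trunc",
) -> AgreementReport:
    """Compute the full agreement report for one cohort of raters.

    ``machine_pred`` holds centered per-odorant machine predictions; it is
    correlated against the pooled per-odorant median VAS.  Subject pairs
    need at least ``min_common`` odorants in common; subjects with a single
    session are excluded from test-retest only.
    """
    frame = ratings.to_frame()
    vectors = _subject_vectors(frame)
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    median = frame.groupby("odorant")["vas"].median()

    subjects = list(vectors.index)
    pair_rs = []
    for i in range(len(subjects)):
        for j in range(i + 1, len(subjects)):
            a, b = vectors.iloc[i], vectors.iloc[j]
            common = a.notna() & b.notna()
            if common.sum() >= min_common:
                pair_rs.append(stats.pearsonr(a[common], b[common])[0])
    if not pair_rs:
        raise ValueError(f"no subject pair shares {min_common} odorants")

    to_median = {}
    for s in subjects:
        vec = vectors.loc[s].dropna()
        if len(vec) >= min_common:
            to_median[s] = stats.pearsonr(vec, median.loc[vec.index])[0]
    to_median = pd.Series(to_median, name="subject_to_median_r")

    by_session = frame.groupby(["subject", "session", "odorant"])["vas"].mean().unstack(
        "odorant"
    )
    retest = []
    for s in subjects:
        try:
            s1, s2 = by_session.loc[(s, 1)], by_session.loc[(s, 2)]
        except KeyError:
            continue  # single-session subject: excluded from test-retest only
        common = s1.notna() & s2.notna()
        if common.sum() >= min_common:
            retest.append(stats.pearsonr(s1[common], s2[common])[0])

    common_od = [o for o in machine_pred.index if o in median.index]
    if len(common_od) < min_common:
        raise ValueError("too few odorants shared by machine predictions and ratings")
    machine_r, machine_p = stats.pearsonr(
        machine_pred.loc[common_od], median.loc[common_od]
    )

    human_to_median_r = float(to_median.mean())
    return AgreementReport(
        pairwise_human_r=float(np.mean(pair_rs)),
        human_to_median_r=human_to_median_r,
        test_retest_r=float(np.mean(retest)) if retest else float("nan"),
        machine_human_r=float(machine_r),
        machine_human_p=float(machine_p),
        percent_of_human=machine_human_percent(
            float(machine_r), human_to_median_r, mode=rounding
        ),
        n_subjects=len(subjects),
        n_pairs=len(pair_rs),
        rounding=rounding,
        per_subject_to_median=to_median,
    )
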