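"""ROC/AUC evaluation of affinity scores as predictors of TF binding.

Positives are sequences a factor is known to bind (e.g. ChIP-seq peaks),
negatives are control sequences.  Each predictor -- TBA, or occupancy at each
cutoff of a grid -- assigns every sequence one score; AUC is computed exactly
via the Mann-Whitney U statistic (tie-safe, and -inf "no predicted site"
scores simply rank below all finite scores).  A full sweep yields one TBA
record plus one record per cutoff for every (experiment, PWM) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from affinityscan.affinity import (
    CutoffGrid,
    NoScorableWindowError,
    SequenceRecord,
    occupancy,
    tba,
)
from affinityscan.pwm import PWM, Background


@dataclass
class LabeledScores:
    """Predictor scores for bound (positive) and control (negative) sequences."""

    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, dtype=float)
        self.negatives = np.asarray(self.negatives, dtype=float)
        if self.positives.size == 0 or self.negatives.size == 0:
            raise ValueError("both positive and negative score lists must be non-empty")


@dataclass(frozen=True)
class AucRecord:
    pwm_id: str
    experiment_id: str
    predictor: str  # "tba" or "occupancy@C"
    cutoff: float | None
    auc: float
    p: float


def roc_auc(scores: LabeledScores) -> float:
    """AUC as the normalized Mann-Whitney U: P(pos > neg) + P(tie)/2.

    Equivalent to the area under the empirical ROC curve, computed exactly
    from ranks; ties (including -inf vs -inf) contribute 1/2.
    """
    pos, neg = scores.positives, scores.negatives
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def mann_whitney_p(scores: LabeledScores) -> float:
    """Two-sided Mann-Whitney U p-value (tie-corrected) for pos vs neg."""
    pos, neg = scores.positives, scores.negatives
    if pos.size == neg.size and np.array_equal(np.sort(pos), np.sort(neg)):
        return 1.0
    return float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)


def score_labeled(
    pwm: PWM,
    positives: list[SequenceRecord],
    negatives: list[SequenceRecord],
    bg: Background | None = None,
    predictor: str = "tba",
    cutoff: float | None = None,
) -> LabeledScores:
    """Score both classes with one predictor; unscorable sequences are dropped."""

    def _score(seqs: list[SequenceRecord]) -> np.ndarray:
        vals = []
        for s in seqs:
            try:
                if predictor == "tba":
                    vals.append(tba(pwm, s, bg).value)
                else:
                    vals.append(occupancy(pwm, s, bg, cutoff).value)
            except NoScorableWindowError:
                continue
        return np.array(vals)

    return LabeledScores(positives=_score(positives), negatives=_score(negatives))


def cutoff_sweep(
    pwms: list[PWM],
    experiments: dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]],
    grid: CutoffGrid | None = None,
    bg: Background | None = None,
) -> list[AucRecord]:
    """AUC of TBA and of occupancy at every grid cutoff, per (experiment, PWM).

    With the default 10-point grid this yields 11 records per pair.  Pairs
    whose sequences cannot be scored at all are skipped (reported as absent
    records rather than raising).
    """
    grid = grid or CutoffGrid()
    records: list[AucRecord] = []
    for exp_id, (positives, negatives) in experiments.items():
        for pwm in pwms:
            try:
                scores = score_labeled(pwm, positives, negatives, bg, "tba")
            except ValueError:
                continue  # no scorable sequence in one class
            records.append(
                AucRecord(
                    pwm_id=pwm.name,
                    experiment_id=exp_id,
                    predictor="tba",
                    cutoff=None,
                    auc=roc_auc(scores),
                    p=mann_whitney_p(scores),
                )
            )
            for c in grid:
                scores = score_labeled(pwm, positives, negatives, bg, "occupancy", c)
                records.append(
                    AucRecord(
                        pwm_id=pwm.name,
                        experiment_id=exp_id,
                        predictor=f"occupancy@{c:g}",
                        cutoff=c,
                        auc=roc_auc(scores),
                        p=mann_whitney_p(scores),
                    )
                )
    return records


def filter_uninformative(records: list[AucRecord]) -> tuple[list[AucRecord], int]:
    """Drop (experiment, PWM) pairs with AUC < 0.5 for every predictor.

    Such pairs show no predictive power at any cutoff nor for TBA, indicating
    a mismatched PWM or a bad experiment.  Returns (kept records, number of
    pairs dropped).
    """
    by_pair: dict[tuple[str, str], list[AucRecord]] = {}
    for r in records:
        by_pair.setdefault((r.experiment_id, r.pwm_id), []).append(r)
    kept: list[AucRecord] = []
    dropped = 0
    for recs in by_pair.values():
        if all(r.auc < 0.5 for r in recs):
            dropped += 1
        else:
            kept.extend(recs)
    return kept, dropped


def paired_wilcoxon_auc_delta(a: dict[str, float], b: dict[str, float]) -> tuple[float, pd.Series]:
    """Paired Wilcoxon signed-rank test on per-PWM AUC differences a - b.

    Both inputs map PWM id -> AUC over the same PWM set.  Exact null
    distribution for n <= 25 pairs (when free of zeros/ties), normal
    approximation with continuity correction otherwise.  Returns the
    two-sided p-value and the per-PWM delta series.
    """
    if set(a) != set(b):
        raise ValueError("PWM sets differ between the two AUC collections")
    pwm_ids = sorted(a)
    deltas = pd.Series([a[k] - b[k] for k in pwm_ids], index=pwm_ids, name="auc_delta")
    nonzero = deltas[deltas != 0]
    if nonzero.empty:
        return 1.0, deltas
    if len(nonzero) <= 25 and len(set(np.abs(nonzero))) == len(nonzero):
        res = stats.wilcoxon(nonzero.to_numpy(), alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(nonzero.to_numpy(), alternative="two-sided", method="approx", correction=True)
    return float(res.pvalue), deltas


def auc_table(records: list[AucRecord]) -> pd.DataFrame:
    """Long-format DataFrame of AUC records (one row per record)."""
    return pd.DataFrame(
        [
            {
                "pwm": r.pwm_id,
                "experiment": r.experiment_id,
                "predictor": r.predictor,
                "cutoff": r.cutoff,
                "auc": r.auc,
                "p": r.p,
            }
            for r in records
        ]
    )


def mean_auc_per_predictor(records: list[AucRecord]) -> pd.DataFrame:
    """Per-PWM AUC averaged over experiments, one column per predictor.

    The unweighted mean over experiments; the wide layout mirrors a
    cutoff-sweep heatmap (rows PWMs, columns TBA then increasing cutoffs).
    """
    df = auc_table(records)
    wide = df.pivot_table(index="pwm", columns="predictor", values="auc", aggfunc="mean")
    order = sorted(wide.columns, key=lambda c: (-1.0 if c == "tba" else float(c.split("@")[1])))
    return wide[order]
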