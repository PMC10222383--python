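"""Biometric evaluation: FAR, FRR, accuracy, EER, DET data, cross-validation.

Conventions: a score greater than or equal to the threshold is an accept,
everywhere.  FAR is the percentage of impostor scores accepted, FRR the
percentage of genuine scores rejected; both are step functions of the
threshold (FAR non-increasing, FRR non-decreasing).  The EER is read off
a sweep over the midpoints between consecutive distinct scores, linearly
interpolating between adjacent sweep points when no exact FAR = FRR
crossing exists — which makes the EER invariant under any strictly
monotone transform of the scores.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bundles import Bundle, FoldAssignment
from .errors import InvalidArgumentError
from .model import EncoderConfig, train


@dataclass(frozen=True)
class ScoredSet:
    """Similarity scores with genuine/impostor labels (1 = genuine)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "scores", np.asarray(self.scores, dtype=np.float64)
        )
        object.__setattr__(
            self, "labels", np.asarray(self.labels, dtype=np.int64)
        )
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise InvalidArgumentError("scores and labels must be parallel 1-D")

    @property
    def genuine(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def impostor(self) -> np.ndarray:
        return self.scores[self.labels == 0]


def rates_at(scored: ScoredSet, tau: float) -> tuple[float, float, float]:
    """(FAR %, FRR %, accuracy %) at threshold ``tau`` (accept iff >= tau)."""
    gen, imp = scored.genuine, scored.impostor
    if gen.size == 0 or imp.size == 0:
        raise InvalidArgumentError(
            "both genuine and impostor scores are required"
        )
    far = 100.0 * np.count_nonzero(imp >= tau) / imp.size
    frr = 100.0 * np.count_nonzero(gen < tau) / gen.size
    correct = np.count_nonzero(gen >= tau) + np.count_nonzero(imp < tau)
    acc = 100.0 * correct / (gen.size + imp.size)
    return float(far), float(frr), float(acc)


def det_curve(scored: ScoredSet) -> np.ndarray:
    """(threshold, FAR %, FRR %) rows over the midpoint threshold sweep."""
    s = np.unique(scored.scores)
    taus = np.concatenate(
        [[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]]
    )
    rows = [(float(t), *rates_at(scored, t)[:2]) for t in taus]
    return np.array(rows)


def eer(scored: ScoredSet) -> tuple[float, float, bool]:
    """Equal error rate (%) and its threshold.

    Returns ``(eer_pct, threshold, degenerate)``; ``degenerate`` is True
    when every score is identical, in which case the crossing is taken at
    that single score value (EER 50%).
    """
    curve = det_curve(scored)
    taus, far, frr = curve[:, 0], curve[:, 1], curve[:, 2]
    degenerate = np.unique(scored.scores).size == 1
    diff = far - frr  # non-increasing in tau: +100 at -inf, -100 at +inf
    zero = np.flatnonzero(np.abs(diff) < 1e-12)
    if zero.size:
        i = int(zero[0])
        return float(far[i]), float(taus[i]), degenerate
    i = int(np.flatnonzero(diff < 0)[0])  # first sign change
    d1, d2 = diff[i - 1], diff[i]
    t = d1 / (d1 - d2)
    eer_val = far[i - 1] + t * (far[i] - far[i - 1])
    tau = taus[i - 1] + t * (taus[i] - taus[i - 1])
    return float(eer_val), float(tau), degenerate


@dataclass
class EvalReport:
    """Verification metrics at the classification and policy thresholds."""

    accuracy: float  # % at threshold 0.5
    far: float  # % at threshold 0.5
    frr: float  # % at threshold 0.5
    eer: float  # %
    eer_threshold: float
    accuracy_policy: float = float("nan")  # % at the 0.7 accept policy
    det: list[tuple[float, float, float]] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        doc = json.loads(text)
        doc["det"] = [tuple(r) for r in doc["det"]]
        return cls(**doc)

    def write_det_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["threshold", "FAR_pct", "FRR_pct"])
            wr.writerows(self.det)


def evaluate_scores(
    scored: ScoredSet,
    threshold: float = 0.5,
    policy_threshold: float = 0.7,
) -> EvalReport:
    far, frr, acc = rates_at(scored, threshold)
    eer_val, eer_tau, _ = eer(scored)
    acc_policy = rates_at(scored, policy_threshold)[2]
    return EvalReport(
        accuracy=acc, far=far, frr=frr,
        eer=eer_val, eer_threshold=eer_tau,
        accuracy_policy=acc_policy,
        det=[tuple(r) for r in det_curve(scored)],
    )


def crossval(
    bundles: list[Bundle],
    folds: FoldAssignment,
    config: EncoderConfig,
    threshold: float = 0.5,
    policy_threshold: float = 0.7,
) -> EvalReport:
    """Train/evaluate across folds; report per-fold metrics and their means.

    For each fold the model is trained from scratch on the remaining
    folds (seeded per fold from ``config.seed``) and scored on the
    held-out bundles.  Genuine = positive bundle.
    """
    from dataclasses import replace

    if folds.assignment.size != len(bundles):
        raise InvalidArgumentError("fold assignment does not match bundles")
    per_fold = []
    for f in range(folds.k):
        test_idx = folds.fold_indices(f)
        train_idx = np.flatnonzero(folds.assignment != f)
        fold_cfg = replace(config, seed=(config.seed * 1000 + f) % (2**31))
        result = train([bundles[i] for i in train_idx], fold_cfg)
        test = [bundles[i] for i in test_idx]
        scored = ScoredSet(
            scores=result.model.score_bundles(test),
            labels=np.array([b.label for b in test]),
        )
        rep = evaluate_scores(scored, threshold, policy_threshold)
        per_fold.append(
            {
                "fold": f,
                "accuracy": rep.accuracy,
                "far": rep.far,
                "frr": rep.frr,
                "eer": rep.eer,
                "eer_threshold": rep.eer_threshold,
                "accuracy_policy": rep.accuracy_policy,
            }
        )
    mean = lambda key: float(np.mean([pf[key] for pf in per_fold]))
    return EvalReport(
        accuracy=mean("accuracy"), far=mean("far"), frr=mean("frr"),
        eer=mean("eer"), eer_threshold=mean("eer_threshold"),
        accuracy_policy=mean("accuracy_policy"),
        per_fold=per_fold,
    )
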