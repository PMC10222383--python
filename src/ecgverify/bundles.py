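"""Balanced (n_ref + 1)-sample bundle construction and cross-validation folds.

A bundle pairs ``n_ref`` reference feature matrices from one subject with
a single probe; the label is positive exactly when the probe comes from
the reference subject.  Because references and probes are sampled, the
builder can emit an exactly balanced label mix regardless of how uneven
the per-subject segment counts are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, InvalidArgumentError
from .preprocess import FeatureMatrix


@dataclass(frozen=True)
class Bundle:
    refs: tuple[FeatureMatrix, ...]
    probe: FeatureMatrix
    label: int  # 1 positive (probe matches refs' subject), 0 negative
    ref_subject: str
    probe_subject: str

    def __post_init__(self) -> None:
        if any(r.subject_id != self.ref_subject for r in self.refs):
            raise InvalidArgumentError("refs must all come from ref_subject")
        if self.probe.subject_id != self.probe_subject:
            raise InvalidArgumentError("probe subject mismatch")
        if self.label != int(self.ref_subject == self.probe_subject):
            raise InvalidArgumentError("label inconsistent with subjects")


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    assignment: np.ndarray  # bundle index -> fold index

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def build_bundles(
    dataset: dict[str, list[FeatureMatrix]],
    n_ref: int,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> list[Bundle]:
    """Draw exactly ``n_pos`` positive and ``n_neg`` negative bundles.

    Positive bundles take ``n_ref + 1`` distinct segments from one
    uniformly chosen eligible subject (references plus a same-subject
    probe); negative bundles take ``n_ref`` references from one subject
    and a probe from a uniformly chosen *different* subject.  Segments may
    recur across bundles but never within one.  Deterministic under
    ``seed``.
    """
    if n_ref < 1:
        raise InvalidArgumentError("n_ref must be >= 1")
    if n_pos < 0 or n_neg < 0:
        raise InvalidArgumentError("bundle counts must be >= 0")
    subjects = sorted(dataset)
    rng = np.random.default_rng(seed)

    pos_eligible = [s for s in subjects if len(dataset[s]) >= n_ref + 1]
    ref_eligible = [s for s in subjects if len(dataset[s]) >= n_ref]
    if n_pos > 0 and not pos_eligible:
        worst = min(subjects, key=lambda s: len(dataset[s])) if subjects else "?"
        raise CapacityError(
            f"no subject has >= n_ref+1={n_ref + 1} segments for positive "
            f"bundles (e.g. {worst!r} has {len(dataset.get(worst, []))})"
        )
    if n_neg > 0:
        if len(subjects) < 2:
            raise CapacityError("negative bundles need >= 2 subjects")
        if not ref_eligible:
            raise CapacityError(
                f"no subject has >= n_ref={n_ref} segments for references"
            )

    bundles: list[Bundle] = []
    for _ in range(n_pos):
        s = pos_eligible[rng.integers(len(pos_eligible))]
        idx = rng.choice(len(dataset[s]), size=n_ref + 1, replace=False)
        segs = [dataset[s][i] for i in idx]
        bundles.append(
            Bundle(
                refs=tuple(segs[:n_ref]), probe=segs[n_ref], label=1,
                ref_subject=s, probe_subject=s,
            )
        )
    for _ in range(n_neg):
        s = ref_eligible[rng.integers(len(ref_eligible))]
        others = [t for t in subjects if t != s and len(dataset[t]) >= 1]
        if not others:
            raise CapacityError(f"no other subject with segments besides {s!r}")
        t = others[rng.integers(len(others))]
        ridx = rng.choice(len(dataset[s]), size=n_ref, replace=False)
        pidx = rng.integers(len(dataset[t]))
        bundles.append(
            Bundle(
                refs=tuple(dataset[s][i] for i in ridx),
                probe=dataset[t][pidx], label=0,
                ref_subject=s, probe_subject=t,
            )
        )
    return bundles


def kfold(bundles: list[Bundle], k: int, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition of bundles.

    Bundles are shuffled within each label class and dealt round-robin
    over the concatenated classes, so total fold sizes differ by at most
    one and each fold's label mix tracks the global mix.
    """
    n = len(bundles)
    if k < 2 or k > n:
        raise InvalidArgumentError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero([b.label == 1 for b in bundles])
    neg = np.flatnonzero([b.label == 0 for b in bundles])
    rng.shuffle(pos)
    rng.shuffle(neg)
    order = np.concatenate([pos, neg])
    assignment = np.empty(n, dtype=np.int64)
    assignment[order] = np.arange(n) % k
    return FoldAssignment(k=k, assignment=assignment)


def bundle_manifest(bundles: list[Bundle], n_ref: int, seed: int) -> dict:
    """JSON-serializable description of a bundle set (for replayable runs).

    Segments are referenced by ``(subject_id, position)`` pairs assigned by
    the caller's dataset ordering; raw feature values are not embedded.
    """
    return {
        "n_ref": n_ref,
        "seed": seed,
        "bundles": [
            {
                "ref_subject": b.ref_subject,
                "probe_subject": b.probe_subject,
                "label": b.label,
            }
            for b in bundles
        ],
    }
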