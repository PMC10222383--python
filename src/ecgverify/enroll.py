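"""Enrollment and authentication against stored embedding templates.

Registering a user stores ``n_ref`` encoder embeddings — never raw
signals — in the template repository, so no retraining is needed to add
users.  Authentication encodes the probe through the same shared encoder
and accepts when its mean similarity to the claimed user's templates
reaches the policy threshold (a score exactly at the threshold accepts).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .errors import (
    AlreadyEnrolledError,
    CapacityError,
    IdentityNotFoundError,
    InvalidArgumentError,
)
from .model import SiameseModel
from .preprocess import Segment, featurize
from .sigio import RepositoryFile


@dataclass(frozen=True)
class AuthPolicy:
    """Accept threshold on the similarity score, plus templates per user."""

    threshold: float = 0.7
    n_ref: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise InvalidArgumentError("threshold must be inside (0, 1)")
        if self.n_ref < 1:
            raise InvalidArgumentError("n_ref must be >= 1")


@dataclass(frozen=True)
class AuthDecision:
    claimed_user: str
    score: float
    accepted: bool
    threshold_used: float


def new_repository(model: SiameseModel, n_ref: int) -> RepositoryFile:
    return RepositoryFile(n_ref=n_ref, embed_dim=model.config.embed_dim)


def enroll(
    repo: RepositoryFile,
    user_id: str,
    segments: list[Segment],
    model: SiameseModel,
    preset: str = "",
) -> RepositoryFile:
    """Store the embeddings of the first ``n_ref`` segments for ``user_id``.

    Deterministic: always the first ``n_ref`` usable segments.  The model
    is read-only here; raw segment values are never written to the
    repository.
    """
    if user_id in repo.users:
        raise AlreadyEnrolledError(f"user {user_id!r} is already enrolled")
    if len(segments) < repo.n_ref:
        raise CapacityError(
            f"need >= {repo.n_ref} segments to enroll, got {len(segments)}"
        )
    embeddings = [
        model.encode(featurize(s)) for s in segments[: repo.n_ref]
    ]
    repo.users[user_id] = {
        "embeddings": embeddings,
        "enrolled_at": datetime.now(timezone.utc).isoformat(),
        "preset": preset,
    }
    repo.validate()
    return repo


def authenticate(
    repo: RepositoryFile,
    claimed_user: str,
    probe: Segment,
    model: SiameseModel,
    policy: AuthPolicy | None = None,
) -> AuthDecision:
    """Verify ``probe`` against the claimed identity's stored templates.

    Read-only for both repository and model.  An unknown claimed identity
    raises :class:`IdentityNotFoundError` — it is not a reject, because a
    reject asserts a mismatch against known templates.
    """
    policy = policy or AuthPolicy(n_ref=repo.n_ref)
    if claimed_user not in repo.users:
        raise IdentityNotFoundError(
            f"user {claimed_user!r} is not enrolled"
        )
    probe_emb = model.encode(featurize(probe))
    sims = [
        model.similarity(probe_emb, ref)
        for ref in repo.users[claimed_user]["embeddings"]
    ]
    score = float(np.mean(sims))
    return AuthDecision(
        claimed_user=claimed_user,
        score=score,
        accepted=score >= policy.threshold,
        threshold_used=policy.threshold,
    )
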