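"""Functional repertoire: the set of unique avalanche patterns.

The size of the repertoire — how many distinct sets of ROIs were recruited
by avalanches over a recording — is the flexibility statistic carried into
the cohort analyses.  Repetitions of a pattern are discarded; patterns are
recruitment sets only, with no ordering or size weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .avalanches import AvalancheSet

__all__ = ["FunctionalRepertoire", "functional_repertoire", "pool_subject", "pattern_canonical_form"]


@dataclass
class FunctionalRepertoire:
    unique_patterns: frozenset = field(default_factory=frozenset)
    n_avalanches_seen: int = 0
    n_rois: int = 0
    subject_id: str = ""
    scope: str = "recording"  # or "subject"

    @property
    def size(self) -> int:
        return len(self.unique_patterns)


def pattern_canonical_form(pattern: Iterable[int], n_rois: int | None = None) -> tuple[int, ...]:
    """Canonical order-free token of a recruitment set: sorted index tuple."""
    indices = sorted(set(int(i) for i in pattern))
    if not indices:
        raise ValueError("pattern must be non-empty")
    if indices[0] < 0 or (n_rois is not None and indices[-1] >= n_rois):
        raise ValueError(f"ROI index out of range [0, {n_rois})")
    return tuple(indices)


def functional_repertoire(
    avalanche_set: AvalancheSet, subject_id: str = "", scope: str = "recording"
) -> FunctionalRepertoire:
    """Collect the distinct avalanche patterns of one recording."""
    patterns = frozenset(av.pattern for av in avalanche_set.avalanches)
    return FunctionalRepertoire(
        unique_patterns=patterns,
        n_avalanches_seen=avalanche_set.n_avalanches,
        n_rois=avalanche_set.n_rois,
        subject_id=subject_id,
        scope=scope,
    )


def pool_subject(
    repertoires: Sequence[FunctionalRepertoire], pooling_policy: str = "union"
) -> FunctionalRepertoire | list[int]:
    """Combine the repertoires of a subject's recordings.

    Under ``"union"`` a pattern seen in any recording counts once for the
    subject; under ``"per-recording"`` the individual sizes are returned for
    separate averaging.
    """
    if not repertoires:
        raise ValueError("need at least one repertoire")
    subject_ids = {r.subject_id for r in repertoires}
    if len(subject_ids) > 1:
        raise ValueError(f"repertoires belong to different subjects: {sorted(subject_ids)}")
    n_rois = {r.n_rois for r in repertoires}
    if len(n_rois) > 1:
        raise ValueError(f"mismatched ROI dimensions: {sorted(n_rois)}")
    if pooling_policy == "per-recording":
        return [r.size for r in repertoires]
    if pooling_policy != "union":
        raise ValueError(f"unknown pooling_policy {pooling_policy!r}")
    pooled = frozenset().union(*(r.unique_patterns for r in repertoires))
    return FunctionalRepertoire(
        unique_patterns=pooled,
        n_avalanches_seen=sum(r.n_avalanches_seen for r in repertoires),
        n_rois=repertoires[0].n_rois,
        subject_id=repertoires[0].subject_id,
        scope="subject",
    )
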