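"""Complete-genome triage from assembly metadata.

From each sequencing sample's contig table, one contig is selected as the
complete phage genome when it is longer than 90 kb (strict), flagged viral,
and classified complete; among candidates the highest read coverage wins,
with ties broken by length and then contig id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .errors import InvalidInputError

__all__ = ["ContigRecord", "COMPLETENESS_LEVELS", "select_complete_genomes"]

logger = logging.getLogger(__name__)

COMPLETENESS_LEVELS = ("complete", "high", "medium", "low", "undetermined")


@dataclass(frozen=True)
class ContigRecord:
    """Per-contig assembly metadata for one sample."""

    contig_id: str
    sample_id: str
    length: int
    viral: bool
    coverage: float
    completeness: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidInputError(f"{self.contig_id}: length must be > 0")
        if self.coverage < 0:
            raise InvalidInputError(f"{self.contig_id}: coverage must be >= 0")
        if self.completeness not in COMPLETENESS_LEVELS:
            raise InvalidInputError(
                f"{self.contig_id}: completeness {self.completeness!r} not in "
                f"{COMPLETENESS_LEVELS}"
            )


def select_complete_genomes(
    records: Iterable[ContigRecord],
    min_length: int = 90_000,
) -> dict[str, str]:
    """Pick the complete phage genome contig for each sample.

    Candidates must have length > ``min_length``, be viral, and be classified
    ``complete``; the winner has the highest coverage (ties: longer contig,
    then lexicographically smallest id).  Samples with no candidate are
    omitted and logged.  The result depends only on the input multiset, not
    its order.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("no contig records supplied")
    by_sample: dict[str, list[ContigRecord]] = {}
    for rec in records:
        bucket = by_sample.setdefault(rec.sample_id, [])
        if any(r.contig_id == rec.contig_id for r in bucket):
            raise InvalidInputError(
                f"duplicate contig id {rec.contig_id!r} in sample {rec.sample_id!r}"
            )
        bucket.append(rec)
    selection: dict[str, str] = {}
    for sample in sorted(by_sample):
        candidates = [
            r for r in by_sample[sample]
            if r.length > min_length and r.viral and r.completeness == "complete"
        ]
        if not candidates:
            logger.warning(
                "sample %s: no contig passes the complete-genome criteria", sample
            )
            continue
        winner = min(
            candidates, key=lambda r: (-r.coverage, -r.length, r.contig_id)
        )
        selection[sample] = winner.contig_id
    return selection
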