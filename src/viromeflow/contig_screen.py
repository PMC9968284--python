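"""Viral-contig inclusion rules: length filter, pVOG thresholds, dereplication.

Contigs shorter than 1 kb are discarded.  A contig counts as virus-rich when
its number of protein hits against the pVOG database meets a length-stratified
threshold (longer contigs must show more viral protein families).  Redundant
contigs are removed greedily from the longest down, keeping the larger of two
sequences whenever pairwise identity and coverage both exceed 90%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from viromeflow.io_formats import ValidationError, VirusRecord

#: (upper length bound exclusive, required pVOG hits); last class is open-ended
PVOG_THRESHOLDS: tuple[tuple[float, int], ...] = (
    (5_000, 3),
    (10_000, 4),
    (20_000, 5),
    (40_000, 6),
    (60_000, 7),
    (float("inf"), 8),
)


@dataclass(frozen=True)
class PairwiseHit:
    """A pairwise alignment summary between two catalogue sequences.

    ``coverage`` is percent of the *shorter* sequence covered by the
    alignment, since the rule's purpose is containment removal.
    """

    query_id: str
    subject_id: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValidationError(f"self-hit for {self.query_id!r}")
        for name, v in (("identity", self.identity), ("coverage", self.coverage)):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} {v} outside [0, 100]")


def length_filter(
    records: Sequence[VirusRecord], min_len: int = 1000
) -> list[VirusRecord]:
    """Drop contigs shorter than ``min_len`` bp (default: the <1 kb rule).

    The boundary is kept: the rule discards strictly-shorter contigs.
    """
    return [r for r in records if r.length >= min_len]


def pvog_pass(length: int, pvog_hits: int) -> bool:
    """True when a contig of ``length`` bp has enough pVOG hits to count as viral.

    Length classes are half-open [lo, hi) with required hits
    3 (<5 kb), 4 ([5,10) kb), 5 ([10,20) kb), 6 ([20,40) kb),
    7 ([40,60) kb) and 8 (>=60 kb).
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if pvog_hits < 0:
        raise ValueError(f"pvog_hits must be >= 0, got {pvog_hits}")
    for upper, needed in PVOG_THRESHOLDS:
        if length < upper:
            return pvog_hits >= needed
    raise AssertionError("unreachable")  # pragma: no cover


def pvog_filter(records: Sequence[VirusRecord]) -> list[VirusRecord]:
    """Keep records whose (length, pvog_hits) pass :func:`pvog_pass`."""
    return [r for r in records if pvog_pass(r.length, r.pvog_hits)]


def dereplicate(
    records: Sequence[VirusRecord],
    hits: Sequence[PairwiseHit],
    id_thresh: float = 90.0,
    cov_thresh: float = 90.0,
) -> tuple[list[VirusRecord], dict[str, str]]:
    """Remove redundant contigs, keeping the larger of each redundant pair.

    Records are visited greedily by descending length (ties broken
    lexicographically by id, so output is independent of input order).  A
    record is discarded iff it has a pairwise hit with identity AND coverage
    strictly exceeding the thresholds against an already-retained record;
    the returned mapping sends each discarded id to its retained
    representative.
    """
    by_id = {r.virus_id: r for r in records}
    if len(by_id) != len(records):
        raise ValidationError("duplicate virus ids in dereplication input")
    # symmetric adjacency of redundant pairs above the thresholds
    adjacent: dict[str, set[str]] = {vid: set() for vid in by_id}
    for h in hits:
        for vid in (h.query_id, h.subject_id):
            if vid not in by_id:
                raise ValidationError(f"pairwise hit references unknown id {vid!r}")
        if h.identity > id_thresh and h.coverage > cov_thresh:
            adjacent[h.query_id].add(h.subject_id)
            adjacent[h.subject_id].add(h.query_id)

    order = sorted(records, key=lambda r: (-r.length, r.virus_id))
    retained_ids: set[str] = set()
    retained: list[VirusRecord] = []
    discarded: dict[str, str] = {}
    for rec in order:
        rep = next(
            (
                other
                for other in sorted(adjacent[rec.virus_id])
                if other in retained_ids
            ),
            None,
        )
        if rep is None:
            retained_ids.add(rec.virus_id)
            retained.append(rec)
        else:
            discarded[rec.virus_id] = rep
    return retained, discarded


def screen_catalog(
    records: Sequence[VirusRecord],
    hits: Sequence[PairwiseHit] = (),
    min_len: int = 1000,
    id_thresh: float = 90.0,
    cov_thresh: float = 90.0,
) -> tuple[list[VirusRecord], dict[str, str]]:
    """Full screen: length filter, pVOG thresholds, then dereplication."""
    kept = pvog_filter(length_filter(records, min_len))
    kept_ids = {r.virus_id for r in kept}
    usable = [
        h for h in hits if h.query_id in kept_ids and h.subject_id in kept_ids
    ]
    return dereplicate(kept, usable, id_thresh, cov_thresh)


def read_pairwise_hits(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> list[PairwiseHit]:
    """Read pairwise hits from 4-column TSV or 12-column BLAST outfmt 6.

    The 4-column dialect is (query, subject, identity, coverage).  For
    outfmt 6 the coverage is computed as alignment length over the shorter
    sequence's length, which requires ``lengths``.  Self-hits are skipped.
    """
    hits: list[PairwiseHit] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == parts[1]:
                continue
            if len(parts) == 4:
                q, s, ident, cov = parts
                hits.append(
                    PairwiseHit(q, s, float(ident), float(cov))
                )
            elif len(parts) >= 12:
                q, s = parts[0], parts[1]
                ident = float(parts[2])
                aln_len = int(parts[3])
                if lengths is None:
                    raise ValidationError(
                        f"{path}: line {lineno}: BLAST tabular input needs "
                        "sequence lengths to derive coverage"
                    )
                try:
                    shorter = min(lengths[q], lengths[s])
                except KeyError as exc:
                    raise ValidationError(
                        f"{path}: line {lineno}: unknown id {exc.args[0]!r}"
                    ) from None
                cov = min(100.0, 100.0 * aln_len / shorter)
                hits.append(PairwiseHit(q, s, ident, cov))
            else:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 4 or >=12 columns, "
                    f"got {len(parts)}"
                )
    return hits
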