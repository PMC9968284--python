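"""Presence/absence calling from mapped reads and breadth of coverage.

A virus is deemed truly present in a sample — not a spurious detection —
when at least 10 reads map to it AND those reads span a length-dependent
fraction of the contig: 50% for contigs under 5 kb, 30% for contigs of
5-20 kb, and 10% for contigs of 20 kb and longer.  Shorter contigs demand
proportionally more breadth because a handful of reads can easily cover a
tenth of a short sequence by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from viromeflow.io_formats import AbundanceMatrix, ValidationError, VirusRecord

MIN_READS = 10


@dataclass(frozen=True)
class CoverageEvidence:
    """Mapped-read count and breadth of coverage for one (virus, sample) cell."""

    virus_id: str
    sample_id: str
    mapped_reads: int
    breadth: float

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValidationError(
                f"({self.virus_id}, {self.sample_id}): negative mapped_reads"
            )
        if not 0.0 <= self.breadth <= 1.0:
            raise ValidationError(
                f"({self.virus_id}, {self.sample_id}): breadth {self.breadth} "
                "outside [0, 1]"
            )


def breadth_from_depth(depth: Sequence[int] | np.ndarray) -> float:
    """Breadth of coverage: fraction of positions with depth >= 1."""
    arr = np.asarray(depth)
    if arr.size == 0:
        raise ValueError("depth vector must have length >= 1")
    if (arr < 0).any():
        raise ValueError("depth values must be non-negative")
    return float(np.count_nonzero(arr >= 1) / arr.size)


def breadth_threshold(length: int) -> float:
    """Minimum breadth required for a contig of ``length`` bp."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if length < 5_000:
        return 0.50
    if length < 20_000:
        return 0.30
    return 0.10


def call_presence(length: int, mapped_reads: int, breadth: float) -> bool:
    """True iff >= 10 mapped reads and breadth meets the length-class minimum."""
    if not 0.0 <= breadth <= 1.0:
        raise ValueError(f"breadth {breadth} outside [0, 1]")
    if mapped_reads < 0:
        raise ValueError(f"mapped_reads must be >= 0, got {mapped_reads}")
    return mapped_reads >= MIN_READS and breadth >= breadth_threshold(length)


def build_presence(
    evidence: Iterable[CoverageEvidence],
    catalog: Sequence[VirusRecord],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply :func:`call_presence` over an evidence set.

    Returns a boolean virus-by-sample DataFrame covering every catalogue
    virus; cells without evidence are absent.  Evidence for a virus not in
    the catalogue is a validation error.
    """
    lengths = {r.virus_id: r.length for r in catalog}
    evidence = list(evidence)
    for ev in evidence:
        if ev.virus_id not in lengths:
            raise ValidationError(
                f"evidence references unknown virus {ev.virus_id!r}"
            )
    if sample_ids is None:
        sample_ids = sorted({ev.sample_id for ev in evidence})
    presence = pd.DataFrame(
        False,
        index=[r.virus_id for r in catalog],
        columns=list(sample_ids),
        dtype=bool,
    )
    for ev in evidence:
        if ev.sample_id not in presence.columns:
            raise ValidationError(
                f"evidence references unknown sample {ev.sample_id!r}"
            )
        if call_presence(lengths[ev.virus_id], ev.mapped_reads, ev.breadth):
            presence.loc[ev.virus_id, ev.sample_id] = True
    return presence


def mask_counts(counts: AbundanceMatrix, presence: pd.DataFrame) -> AbundanceMatrix:
    """Zero out count cells whose virus was not called present in the sample.

    Masking happens before relative-abundance conversion so spurious
    low-level detections never contribute to composition.
    """
    aligned = presence.reindex(
        index=counts.counts.index, columns=counts.counts.columns, fill_value=False
    )
    return AbundanceMatrix(counts.counts.where(aligned, 0.0))


# ---------------------------------------------------------------------------
# depth-table input (sparse samtools-depth dialect)


def read_depth_table(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a 3-column (contig, 1-based position, depth) TSV for one sample.

    Positions with zero depth may be omitted; the catalogue length completes
    each vector.  Returns a dict mapping virus id to its full depth vector.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            vid, pos_s, depth_s = parts
            if vid not in lengths:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown contig {vid!r}"
                )
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-integer position/depth"
                ) from None
            if not 1 <= pos <= lengths[vid]:
                raise ValidationError(
                    f"{path}: line {lineno}: position {pos} outside contig "
                    f"{vid!r} of length {lengths[vid]}"
                )
            if vid not in vectors:
                vectors[vid] = np.zeros(lengths[vid], dtype=int)
            vectors[vid][pos - 1] = depth
    return vectors


def evidence_from_depth(
    sample_id: str,
    vectors: Mapping[str, np.ndarray],
    mapped_reads: Mapping[str, int],
) -> list[CoverageEvidence]:
    """Combine per-contig depth vectors and read counts into evidence rows."""
    out = []
    for vid, vec in vectors.items():
        out.append(
            CoverageEvidence(
                virus_id=vid,
                sample_id=sample_id,
                mapped_reads=int(mapped_reads.get(vid, 0)),
                breadth=breadth_from_depth(vec),
            )
        )
    return out


def read_evidence_table(path: str | Path) -> list[CoverageEvidence]:
    """Read a (virus_id, sample_id, mapped_reads, breadth) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"virus_id": str, "sample_id": str})
    needed = {"virus_id", "sample_id", "mapped_reads", "breadth"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        CoverageEvidence(r.virus_id, r.sample_id, int(r.mapped_reads), float(r.breadth))
        for r in df.itertuples(index=False)
    ]


def write_evidence_table(
    evidence: Sequence[CoverageEvidence], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "virus_id": [e.virus_id for e in evidence],
            "sample_id": [e.sample_id for e in evidence],
            "mapped_reads": [e.mapped_reads for e in evidence],
            "breadth": [f"{e.breadth:.6f}" for e in evidence],
        }
    ).to_csv(path, sep="\t", index=False)
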