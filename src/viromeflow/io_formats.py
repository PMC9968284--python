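"""Tabular readers/writers, domain records and cohort metadata validation.

File conventions: virus catalogues and count matrices are TSV (viruses as
rows, samples as columns), sample metadata is CSV, configuration is YAML.
All text is UTF-8 with '.' as the decimal separator. Readers reject malformed
rows with the offending row number rather than coercing them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("viromeflow")

CONDITIONS = ("Control", "CD", "UC")

#: sentinel for taxonomy / lifecycle that could not be assigned.  Unknown is a
#: first-class state: only a minority of gut-virome contigs get taxonomic
#: (26.6% in the cohort this mirrors) or lifecycle (13.7%) assignments, so
#: "unknown" must never collapse onto "non-lysogenic".
UNKNOWN = "unknown"


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Contents parsed but violate a domain invariant."""


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class VirusRecord:
    """One virus-catalogue entry (an assembled contig accepted as viral).

    ``lysogenic`` is True/False when lifecycle genes were assessed and None
    when unknown; ``family``/``viral_class`` use :data:`UNKNOWN` when
    unassigned.  ``pvog_hits`` is the count of protein hits against the
    Prokaryotic Viral Orthologous Groups database.
    """

    virus_id: str
    length: int
    circular: bool = False
    family: str = UNKNOWN
    viral_class: str = UNKNOWN
    lysogenic: bool | None = None
    cluster_id: str | None = None
    pvog_hits: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(
                f"virus {self.virus_id!r}: length must be >= 1, got {self.length}"
            )
        if self.pvog_hits < 0:
            raise ValidationError(
                f"virus {self.virus_id!r}: pvog_hits must be >= 0, got {self.pvog_hits}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced faecal sample: subject, condition, time point."""

    sample_id: str
    subject_id: str
    condition: str
    timepoint: int
    collection_day: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"not one of {CONDITIONS}"
            )
        if self.timepoint not in (1, 2, 3):
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint must be 1, 2 or 3, "
                f"got {self.timepoint}"
            )
        if self.timepoint == 1 and self.collection_day != 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint 1 must have "
                f"collection_day 0, got {self.collection_day}"
            )
        if self.collection_day < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative collection_day"
            )


class CohortDesign:
    """Maps samples to subjects and conditions; 1-3 time points per subject."""

    def __init__(self, samples: Sequence[SampleRecord]):
        self.samples: list[SampleRecord] = list(samples)
        seen_ids: set[str] = set()
        by_subject: dict[str, list[SampleRecord]] = {}
        seen_pairs: set[tuple[str, int]] = set()
        for s in self.samples:
            if s.sample_id in seen_ids:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen_ids.add(s.sample_id)
            pair = (s.subject_id, s.timepoint)
            if pair in seen_pairs:
                raise ValidationError(
                    f"subject {s.subject_id!r} has two samples at timepoint "
                    f"{s.timepoint}"
                )
            seen_pairs.add(pair)
            by_subject.setdefault(s.subject_id, []).append(s)
        for subj, recs in by_subject.items():
            if len(recs) > 3:
                raise ValidationError(f"subject {subj!r} has >3 time points")
            conds = {r.condition for r in recs}
            if len(conds) > 1:
                raise ValidationError(
                    f"subject {subj!r} has inconsistent conditions {sorted(conds)}"
                )
            recs.sort(key=lambda r: r.timepoint)
        self.by_subject: dict[str, list[SampleRecord]] = by_subject

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.by_subject)

    def condition_of_subject(self, subject_id: str) -> str:
        return self.by_subject[subject_id][0].condition

    def condition_of_sample(self, sample_id: str) -> str:
        return self._sample_index()[sample_id].condition

    def subject_of_sample(self, sample_id: str) -> str:
        return self._sample_index()[sample_id].subject_id

    def _sample_index(self) -> dict[str, SampleRecord]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {s.sample_id: s for s in self.samples}
            self._idx = idx
        return idx

    def subjects_by_condition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in CONDITIONS}
        for subj in self.subject_ids:
            out[self.condition_of_subject(subj)].append(subj)
        return {c: v for c, v in out.items() if v}

    def subset(self, sample_ids: Iterable[str]) -> "CohortDesign":
        keep = set(sample_ids)
        return CohortDesign([s for s in self.samples if s.sample_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject_id": [s.subject_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "collection_day": [s.collection_day for s in self.samples],
            }
        )

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CohortDesign) and self.samples == other.samples


class AbundanceMatrix:
    """Virus-by-sample count matrix with relative-abundance and presence views.

    Samples whose counts are all zero are flagged (``zero_samples``) and
    excluded from the relative-abundance view with a logged warning — they are
    never silently normalised.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise ValidationError("duplicate virus ids in count matrix")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        arr = counts.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("negative counts in matrix")
        self.counts = counts.astype(float)

    @property
    def virus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def zero_samples(self) -> list[str]:
        totals = self.counts.sum(axis=0)
        return list(totals.index[totals == 0])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; all-zero samples are dropped with a warning."""
        zeros = self.zero_samples
        if zeros:
            logger.warning(
                "excluding %d all-zero sample(s) from relative abundances: %s",
                len(zeros),
                ", ".join(zeros),
            )
        sub = self.counts.drop(columns=zeros)
        return sub / sub.sum(axis=0)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AbundanceMatrix) and self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# catalogue I/O

_CATALOG_COLUMNS = (
    "virus_id",
    "length",
    "circular",
    "family",
    "viral_class",
    "lysogenic",
    "cluster_id",
    "pvog_hits",
)


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise FormatError(f"row {row}: cannot parse {column}={value!r} as boolean")


def _parse_optional_bool(value: str, row: int, column: str) -> bool | None:
    v = value.strip().lower()
    if v in ("", UNKNOWN, "na", "nan", "none"):
        return None
    return _parse_bool(value, row, column)


def read_catalog(path: str | Path) -> list[VirusRecord]:
    """Read a virus catalogue TSV into validated :class:`VirusRecord` rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _CATALOG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records: list[VirusRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        vid = row.virus_id
        if vid in seen:
            raise ValidationError(f"{path}: duplicate virus_id {vid!r} at row {i}")
        seen.add(vid)
        try:
            length = int(row.length)
        except ValueError:
            raise FormatError(
                f"{path}: row {i}: non-numeric length {row.length!r}"
            ) from None
        try:
            pvog = int(row.pvog_hits)
        except ValueError:
            raise FormatError(
                f"{path}: row {i}: non-numeric pvog_hits {row.pvog_hits!r}"
            ) from None
        records.append(
            VirusRecord(
                virus_id=vid,
                length=length,
                circular=_parse_bool(row.circular, i, "circular"),
                family=row.family.strip() or UNKNOWN,
                viral_class=row.viral_class.strip() or UNKNOWN,
                lysogenic=_parse_optional_bool(row.lysogenic, i, "lysogenic"),
                cluster_id=row.cluster_id.strip() or None,
                pvog_hits=pvog,
            )
        )
    return records


def write_catalog(records: Sequence[VirusRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "virus_id": [r.virus_id for r in records],
            "length": [r.length for r in records],
            "circular": [r.circular for r in records],
            "family": [r.family for r in records],
            "viral_class": [r.viral_class for r in records],
            "lysogenic": [
                "" if r.lysogenic is None else str(r.lysogenic) for r in records
            ],
            "cluster_id": [r.cluster_id or "" for r in records],
            "pvog_hits": [r.pvog_hits for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts matrix and metadata I/O


def read_counts_matrix(path: str | Path) -> AbundanceMatrix:
    """Read a virus-by-sample counts TSV (viruses as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric values in count matrix")
    neg = np.argwhere(arr < 0)
    if neg.size:
        r, c = neg[0]
        raise FormatError(
            f"{path}: negative count at row {r + 2} (virus {df.index[r]!r}, "
            f"sample {df.columns[c]!r})"
        )
    return AbundanceMatrix(df)


def write_counts_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    # preserve integer counts textually when they are integral
    if np.allclose(out.to_numpy(), np.round(out.to_numpy())):
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="virus_id")


_METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "condition",
    "timepoint",
    "collection_day",
)


def read_metadata(path: str | Path) -> CohortDesign:
    """Read sample metadata CSV into a validated :class:`CohortDesign`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tp = int(row.timepoint)
            day = int(row.collection_day)
        except ValueError:
            raise FormatError(
                f"{path}: row {i}: non-numeric timepoint/collection_day"
            ) from None
        samples.append(
            SampleRecord(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                condition=row.condition,
                timepoint=tp,
                collection_day=day,
            )
        )
    return CohortDesign(samples)


def write_metadata(design: CohortDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def reconcile(
    matrix: AbundanceMatrix, design: CohortDesign, strict: bool = True
) -> tuple[AbundanceMatrix, CohortDesign]:
    """Check matrix sample ids against metadata.

    In strict mode (default) any discrepancy raises; in lenient mode the
    intersection is taken with a logged warning.  Silent sample drops would
    corrupt cohort statistics, hence strict is the default.
    """
    mat_ids = set(matrix.sample_ids)
    meta_ids = set(design.sample_ids)
    if mat_ids == meta_ids:
        return matrix, design
    if strict:
        only_mat = sorted(mat_ids - meta_ids)
        only_meta = sorted(meta_ids - mat_ids)
        raise ValidationError(
            "matrix/metadata sample mismatch: "
            f"matrix-only={only_mat}, metadata-only={only_meta}"
        )
    common = sorted(mat_ids & meta_ids)
    if not common:
        raise ValidationError("matrix and metadata share no samples")
    logger.warning(
        "lenient reconciliation: keeping %d shared sample(s), dropping %d",
        len(common),
        len(mat_ids ^ meta_ids),
    )
    kept_cols = [s for s in matrix.sample_ids if s in set(common)]
    return AbundanceMatrix(matrix.counts[kept_cols]), design.subset(common)


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "min_contig_length": 1000,
    "derep_identity": 90.0,
    "derep_coverage": 90.0,
    "min_reads": 10,
    "metric": "canberra",
    "permutations": 999,
    "bootstrap_subjects": 10,
    "bootstrap_reps": 20,
    "rarefaction_reps": 100,
    "strict": True,
}


def read_config(path: str | Path | None) -> dict:
    """Load YAML config merged over :data:`DEFAULT_CONFIG`."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise FormatError(f"{path}: config must be a YAML mapping")
        cfg.update(user)
    return cfg
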