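"""Longitudinal persistence and fluctuation of personal viromes.

Each subject's detected viruses are classified by how many of the subject's
time points they appear in: the persistent personal virome (all three time
points), intermittent viruses (two), and transients (one).  Percentages are
taken over the subject's union of detected viruses.  Three-time-point
abundance trajectories are expressed as ternary coordinates (three
percentages summing to 100), and intra- vs inter-personal virome
dissimilarity is compared with a Wilcoxon rank-sum test on Bray-Curtis
distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from viromeflow.io_formats import CohortDesign, ValidationError
from viromeflow.diversity import distance_matrix

logger = logging.getLogger("viromeflow")


def persistence_classes(
    presence: pd.DataFrame, design: CohortDesign
) -> pd.DataFrame:
    """Per-subject persistence decomposition of the detected virome.

    For every subject with >= 2 samples, each virus ever detected in that
    subject is classified by its number of detection time points.  Percentages
    are over the subject's detected-virus union.  ``pct_in_3`` is only defined
    for subjects with exactly 3 samples (NaN otherwise); subjects with a
    single sample are excluded with a log message.
    """
    rows = []
    for subj in design.subject_ids:
        recs = design.by_subject[subj]
        if len(recs) < 2:
            logger.info("subject %s has one sample; excluded from persistence", subj)
            continue
        sub = presence[[r.sample_id for r in recs]]
        n_tp = sub.sum(axis=1).astype(int)
        detected = n_tp[n_tp > 0]
        total = len(detected)
        n3 = int((detected == 3).sum())
        n2 = int((detected == 2).sum())
        n1 = int((detected == 1).sum())
        row = {
            "subject_id": subj,
            "condition": design.condition_of_subject(subj),
            "n_timepoints": len(recs),
            "n_detected_total": total,
            "n_in_3": n3,
            "n_in_2": n2,
            "n_in_1": n1,
        }
        if total > 0:
            row["pct_in_3"] = 100.0 * n3 / total if len(recs) == 3 else np.nan
            row["pct_in_2"] = 100.0 * n2 / total
            row["pct_in_1"] = 100.0 * n1 / total
        else:
            row["pct_in_3"] = row["pct_in_2"] = row["pct_in_1"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def richness_by_condition(
    presence: pd.DataFrame, design: CohortDesign, three_timepoint_only: bool = True
) -> pd.DataFrame:
    """Unrarefied per-sample richness (number of detected viruses), by condition.

    By default restricted to samples from subjects with all three time points
    available, matching the longitudinal analysis set.
    """
    rows = []
    for subj in design.subject_ids:
        recs = design.by_subject[subj]
        if three_timepoint_only and len(recs) != 3:
            continue
        for r in recs:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "subject_id": subj,
                    "condition": r.condition,
                    "richness": int(presence[r.sample_id].sum()),
                }
            )
    return pd.DataFrame(rows)


def ternary_coords(
    rel_abund: pd.DataFrame, design: CohortDesign, subject: str
) -> pd.DataFrame:
    """Ternary decomposition of a subject's three-time-point trajectories.

    For each virus detected (nonzero relative abundance) in at least one of
    the subject's three time points, returns p1/p2/p3: the percentage of the
    virus's summed within-sample relative abundance contributed by each time
    point.  A virus equally abundant at all three sits at (33.3, 33.3, 33.3).
    """
    recs = design.by_subject.get(subject)
    if recs is None:
        raise ValidationError(f"unknown subject {subject!r}")
    if len(recs) != 3:
        raise ValidationError(
            f"subject {subject!r} has {len(recs)} time points; ternary "
            "decomposition needs exactly 3"
        )
    cols = [r.sample_id for r in sorted(recs, key=lambda r: r.timepoint)]
    missing = [c for c in cols if c not in rel_abund.columns]
    if missing:
        raise ValidationError(
            f"subject {subject!r}: sample(s) {missing} absent from abundances"
        )
    ra = rel_abund[cols]
    totals = ra.sum(axis=1)
    keep = totals > 0
    pct = 100.0 * ra.loc[keep].div(totals[keep], axis=0)
    out = pct.copy()
    out.columns = ["p1", "p2", "p3"]
    out.insert(0, "subject_id", subject)
    out.insert(1, "condition", design.condition_of_subject(subject))
    return out.rename_axis("virus_id").reset_index()


@dataclass
class DissimilarityResult:
    """Intra- vs inter-personal distance sets and their rank-sum comparison."""

    pairs: pd.DataFrame  # pair_type, sample/subject ids, distance
    statistic: float
    p_value: float

    @property
    def intra(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["pair_type"] == "intra", "distance"].to_numpy()

    @property
    def inter(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["pair_type"] == "inter", "distance"].to_numpy()


def intra_inter_dissimilarity(
    rel_abund: pd.DataFrame,
    design: CohortDesign,
    metric: str = "bray_curtis",
    condition: str | None = None,
) -> DissimilarityResult:
    """All within-subject vs between-subject sample distances, with a
    two-sided Wilcoxon rank-sum test comparing the two sets.

    ``condition`` restricts the analysis to one cohort (condition-stratified
    variant); subjects contribute intra pairs only when they have >= 2
    samples with abundance data.
    """
    samples = [
        s
        for s in design.samples
        if s.sample_id in rel_abund.columns
        and (condition is None or s.condition == condition)
    ]
    if len(samples) < 3:
        raise ValidationError("too few samples for dissimilarity analysis")
    ids = [s.sample_id for s in samples]
    subj_of = {s.sample_id: s.subject_id for s in samples}
    dm = distance_matrix(rel_abund[ids], metric)
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = ids[i], ids[j]
        rows.append(
            {
                "pair_type": "intra" if subj_of[a] == subj_of[b] else "inter",
                "sample_a": a,
                "sample_b": b,
                "subject_a": subj_of[a],
                "subject_b": subj_of[b],
                "distance": float(dm.values[i, j]),
            }
        )
    pairs = pd.DataFrame(rows)
    intra = pairs.loc[pairs["pair_type"] == "intra", "distance"]
    inter = pairs.loc[pairs["pair_type"] == "inter", "distance"]
    if intra.empty:
        raise ValidationError("no within-subject sample pairs available")
    stat, p = stats.ranksums(intra, inter)
    return DissimilarityResult(pairs, float(stat), float(p))
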