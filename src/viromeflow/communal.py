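"""Communal-virus sharing: who carries what, and how sharing differs by condition.

A virus is "communal" when it is detected in two or more cohort subjects.
Because cohorts differ in size, sharing between conditions is compared by
bootstrap subsampling: a fixed number of subjects per condition (10 in the
study design) is drawn repeatedly (20 times), each subject contributing a
single randomly chosen time point, and the number of previously flagged
communal viruses detected in at least k of the subsample is recorded for
each k.  Sharing-strata summaries bin viruses by the fraction of the total
cohort carrying them and report mean and cumulative relative abundances per
condition, optionally restricted to lysogenic phages or a single family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from viromeflow.io_formats import CohortDesign, ValidationError, VirusRecord

logger = logging.getLogger("viromeflow")

#: sharing-fraction strata, left-open/right-closed, partitioning (0, 1]
DEFAULT_STRATA: tuple[tuple[float, float], ...] = (
    (0.0, 0.1),
    (0.1, 0.2),
    (0.2, 0.3),
    (0.3, 0.4),
    (0.4, 1.0),
)


def _stratum_label(lo: float, hi: float) -> str:
    return f"{lo * 100:g}-{hi * 100:g}%"


def subject_presence(
    presence: pd.DataFrame,
    design: CohortDesign,
    mode: str = "union",
    timepoint: int | str = "random",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Collapse a virus-by-sample presence matrix to virus-by-subject.

    ``mode='union'``: a subject carries a virus if it is detected at any of
    the subject's time points (used for total-cohort sharing fractions).
    ``mode='single_timepoint'``: only the selected time point counts —
    ``timepoint`` is 1/2/3 or ``'random'`` (one uniform draw per subject);
    subjects lacking a fixed requested time point are excluded with a warning.
    """
    if mode not in ("union", "single_timepoint"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [s for s in design.sample_ids if s not in presence.columns]
    if missing:
        raise ValidationError(
            f"presence matrix lacks {len(missing)} design sample(s), "
            f"e.g. {missing[0]!r}"
        )
    if mode == "single_timepoint" and timepoint == "random":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
    cols: dict[str, pd.Series] = {}
    for subj in design.subject_ids:
        recs = design.by_subject[subj]
        if mode == "union":
            sel = [r.sample_id for r in recs]
            cols[subj] = presence[sel].any(axis=1)
        else:
            if timepoint == "random":
                rec = recs[int(rng.integers(len(recs)))]
            else:
                match = [r for r in recs if r.timepoint == int(timepoint)]
                if not match:
                    logger.warning(
                        "subject %s has no timepoint %s sample; excluded",
                        subj,
                        timepoint,
                    )
                    continue
                rec = match[0]
            cols[subj] = presence[rec.sample_id]
    return pd.DataFrame(cols)


def communal_set(subj_presence: pd.DataFrame) -> pd.DataFrame:
    """Per-virus sharing profile over the cohort.

    Returns a DataFrame indexed by virus with ``subjects_detected``,
    ``sharing_fraction`` (of all subjects in the input) and ``is_communal``
    (detected in >= 2 subjects).
    """
    n_subjects = subj_presence.shape[1]
    if n_subjects < 2:
        raise ValidationError("communal analysis needs >= 2 subjects")
    detected = subj_presence.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "subjects_detected": detected,
            "sharing_fraction": detected / n_subjects,
            "is_communal": detected >= 2,
        }
    )


def bootstrap_sharing(
    presence: pd.DataFrame,
    design: CohortDesign,
    communal_ids: Sequence[str],
    n_subjects: int = 10,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap sharing spectra per condition.

    Each replicate draws ``n_subjects`` subjects per condition without
    replacement, each represented by one random time point, and counts how
    many of the previously flagged communal viruses are detected in >= k of
    the subsample, for k = 1..n_subjects.  Returns a long DataFrame
    (condition, replicate, k, count).

    Replicates use independent sub-streams derived from the master seed, so
    increasing ``reps`` never changes earlier replicates.
    """
    by_cond = design.subjects_by_condition()
    for cond, subs in by_cond.items():
        if len(subs) < n_subjects:
            raise ValidationError(
                f"condition {cond!r} has only {len(subs)} subjects; "
                f"use n_subjects <= {len(subs)}"
            )
    communal_ids = [v for v in communal_ids if v in presence.index]
    sub = presence.loc[communal_ids]
    streams = np.random.SeedSequence(seed).spawn(reps)
    rows = []
    for rep_i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for cond in sorted(by_cond):
            subjects = by_cond[cond]
            chosen = rng.choice(len(subjects), size=n_subjects, replace=False)
            samples = []
            for idx in chosen:
                recs = design.by_subject[subjects[idx]]
                samples.append(recs[int(rng.integers(len(recs)))].sample_id)
            carried = sub[samples].to_numpy().sum(axis=1)
            for k in range(1, n_subjects + 1):
                rows.append(
                    {
                        "condition": cond,
                        "replicate": rep_i,
                        "k": k,
                        "count": int((carried >= k).sum()),
                    }
                )
    return pd.DataFrame(rows)


def spectrum_summary(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of the bootstrap sharing count per (condition, k)."""
    return (
        spectrum.groupby(["condition", "k"])["count"]
        .agg(["mean", "std"])
        .reset_index()
    )


def compare_spectra(
    spectrum: pd.DataFrame, cond_a: str, cond_b: str, k_min: int = 2
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum on replicate counts, per k >= ``k_min``."""
    out = []
    for k, grp in spectrum[spectrum["k"] >= k_min].groupby("k"):
        a = grp.loc[grp["condition"] == cond_a, "count"].to_numpy()
        b = grp.loc[grp["condition"] == cond_b, "count"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        stat, p = stats.ranksums(a, b)
        out.append({"k": k, "statistic": float(stat), "p_value": float(p)})
    return pd.DataFrame(out)


def assign_strata(
    sharing_fraction: pd.Series,
    strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
) -> pd.Series:
    """Bin sharing fractions into left-open/right-closed strata labels.

    Fractions of exactly 0 (never detected) get no stratum (NaN).
    """
    labels = pd.Series(pd.NA, index=sharing_fraction.index, dtype=object)
    for lo, hi in strata:
        mask = (sharing_fraction > lo) & (sharing_fraction <= hi)
        labels[mask] = _stratum_label(lo, hi)
    return labels


def _subset_ids(
    virus_ids: Sequence[str],
    catalog: Sequence[VirusRecord] | None,
    subset: str,
) -> list[str]:
    if subset == "all":
        return list(virus_ids)
    if catalog is None:
        raise ValidationError(f"subset {subset!r} requires a catalogue")
    by_id = {r.virus_id: r for r in catalog}
    if subset == "lysogenic":
        return [v for v in virus_ids if by_id[v].lysogenic is True]
    if subset.startswith("family="):
        fam = subset.split("=", 1)[1]
        return [v for v in virus_ids if by_id[v].family == fam]
    raise ValueError(f"unknown subset {subset!r}")


def strata_abundance(
    rel_abund: pd.DataFrame,
    profile: pd.DataFrame,
    design: CohortDesign,
    strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    subset: str = "all",
    catalog: Sequence[VirusRecord] | None = None,
) -> pd.DataFrame:
    """Relative abundance of communal viruses by sharing stratum and condition.

    For each stratum (bin of total-cohort sharing fraction) and condition:
    ``mean_ra`` is the mean over member viruses of the virus's average
    relative abundance across that condition's samples, ``cum_ra`` their sum,
    ``n_viruses`` the member count.  Between-condition Student's t-tests are
    run per stratum on the per-virus averaged abundances, with Bonferroni
    adjustment across all tests performed.
    """
    communal = profile[profile["is_communal"]]
    member_ids = _subset_ids(
        [v for v in communal.index if v in rel_abund.index], catalog, subset
    )
    labels = assign_strata(communal.loc[member_ids, "sharing_fraction"], strata)
    cond_samples: dict[str, list[str]] = {}
    for s in design.samples:
        if s.sample_id in rel_abund.columns:
            cond_samples.setdefault(s.condition, []).append(s.sample_id)

    rows = []
    test_rows = []
    for lo, hi in strata:
        label = _stratum_label(lo, hi)
        members = [v for v in member_ids if labels[v] == label]
        per_cond_values: dict[str, np.ndarray] = {}
        for cond in sorted(cond_samples):
            if members:
                vals = (
                    rel_abund.loc[members, cond_samples[cond]]
                    .mean(axis=1)
                    .to_numpy()
                )
            else:
                vals = np.array([])
            per_cond_values[cond] = vals
            rows.append(
                {
                    "stratum": label,
                    "condition": cond,
                    "mean_ra": float(vals.mean()) if vals.size else np.nan,
                    "cum_ra": float(vals.sum()) if vals.size else 0.0,
                    "n_viruses": int(vals.size),
                }
            )
        conds = sorted(per_cond_values)
        for i in range(len(conds)):
            for jj in range(i + 1, len(conds)):
                a, b = per_cond_values[conds[i]], per_cond_values[conds[jj]]
                if len(a) >= 2 and len(b) >= 2:
                    _, p = stats.ttest_ind(a, b)
                    test_rows.append(
                        {
                            "stratum": label,
                            "pair": f"{conds[i]} vs {conds[jj]}",
                            "p_raw": float(p),
                        }
                    )
    summary = pd.DataFrame(rows)
    tests = pd.DataFrame(test_rows)
    if not tests.empty:
        tests["p_bonferroni"] = np.minimum(tests["p_raw"] * len(tests), 1.0)
        summary = summary.merge(
            tests.groupby("stratum")
            .apply(
                lambda g: pd.Series(
                    {
                        "p_raw_min": g["p_raw"].min(),
                        "p_bonferroni_min": g["p_bonferroni"].min(),
                    }
                ),
                include_groups=False,
            )
            .reset_index(),
            on="stratum",
            how="left",
        )
    summary.attrs["tests"] = tests
    return summary
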