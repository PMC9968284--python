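"""Seeded synthetic virome cohorts with the structure the analyses assume.

The generator emulates a longitudinal faecal-virome study: three conditions
(healthy controls, Crohn's disease, ulcerative colitis) sampled at up to
three time points roughly 100 days apart.  Each subject's virome is composed
of three exclusive membership classes per virus:

* **communal** viruses, drawn from a shared pool with condition-specific
  carriage probability (controls carry more of the pool than IBD subjects);
* a **persistent personal virome (PPV)**: private viruses present at each
  time point with a high persistence probability;
* **transient** viruses appearing in exactly one time point.

Abundances are heavy-tailed: each (virus, subject) pair has a lognormal base
abundance with multiplicative per-time-point noise, so persistent viruses
still fluctuate strongly between visits.  Lysogen-flagged viruses get an
abundance boost in IBD subjects.  Read-level coverage evidence is produced
by placing fixed-length reads uniformly along each contig, so breadth of
coverage follows the Lander-Waterman expectation 1 - exp(-R*l/L).

All randomness derives hierarchically from one master seed (catalogue,
per-subject and per-sample streams are independent), so enlarging the cohort
or adding replicates never changes previously generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from viromeflow.contig_screen import PVOG_THRESHOLDS
from viromeflow.detection import CoverageEvidence, write_evidence_table
from viromeflow.io_formats import (
    AbundanceMatrix,
    CohortDesign,
    SampleRecord,
    ValidationError,
    VirusRecord,
    write_catalog,
    write_counts_matrix,
    write_metadata,
)

#: family marginals for the taxonomically assigned minority of the catalogue;
#: tailed phages dominate, with crAss-like phages prominent.
FAMILY_WEIGHTS: dict[str, float] = {
    "Siphoviridae": 0.40,
    "Myoviridae": 0.18,
    "Podoviridae": 0.14,
    "crAss-like": 0.12,
    "Microviridae": 0.10,
    "Virgaviridae": 0.06,
}

_TAILED = {"Siphoviridae", "Myoviridae", "Podoviridae", "crAss-like"}


@dataclass
class SimulationConfig:
    """Study-design and generative parameters for the synthetic cohort.

    Cohort-design defaults mirror the study this package models: 40 control,
    19 CD and 20 UC subjects; 2/1/1 of them respectively donate only two
    samples, so the default cohort has 79 subjects and 233 samples (118
    control, 56 CD, 59 UC), 75 of the subjects with all three time points.
    """

    # cohort design
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"Control": 40, "CD": 19, "UC": 20}
    )
    n_two_timepoint: dict[str, int] = field(
        default_factory=lambda: {"Control": 2, "CD": 1, "UC": 1}
    )
    interval_mean_days: float = 96.0  # approx. 100-day donation intervals
    interval_sd_days: float = 25.0

    # catalogue
    catalog_size: int = 5000
    min_length: int = 1000
    max_length: int = 200_000
    frac_taxonomy: float = 0.266  # fraction with a family assignment
    frac_lysogenic: float = 0.137  # fraction flagged as carrying lysogeny genes
    frac_known_lytic: float = 0.05  # lifecycle assessed, no lysogeny genes
    frac_circular: float = 0.014
    frac_clustered: float = 0.2  # fraction grouped into multi-member VCs

    # community structure
    communal_pool_size: int = 300
    communal_carriage: dict[str, float] = field(
        default_factory=lambda: {"Control": 0.15, "CD": 0.07, "UC": 0.09}
    )
    #: a carried communal virus is detected at any given time point with this
    #: probability — even shared viruses drop in and out of detection
    communal_tp_detect_prob: float = 0.55
    ppv_size: dict[str, int] = field(
        default_factory=lambda: {"Control": 10, "CD": 7, "UC": 7}
    )
    persistence_prob: float = 0.85
    transient_per_timepoint: dict[str, int] = field(
        default_factory=lambda: {"Control": 14, "CD": 18, "UC": 18}
    )

    # abundance model (log scale)
    abundance_sigma_between: float = 2.0  # lognormal spread across virus-subject
    abundance_sigma_within: float = 1.0  # per-time-point multiplicative noise
    lysogen_ibd_log_boost: float = 0.7  # added to lysogens in CD/UC subjects

    # sequencing
    reads_per_sample: int = 50_000
    read_length: int = 150

    def validate(self) -> None:
        for cond, n in self.n_subjects.items():
            if n < 0:
                raise ValidationError(f"n_subjects[{cond}] must be >= 0")
            if self.n_two_timepoint.get(cond, 0) > n:
                raise ValidationError(
                    f"n_two_timepoint[{cond}] exceeds n_subjects[{cond}]"
                )
        if self.catalog_size < 1:
            raise ValidationError("catalog_size must be >= 1")
        for cond, p in self.communal_carriage.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"communal_carriage[{cond}] outside [0,1]")
        if not 0.0 <= self.persistence_prob <= 1.0:
            raise ValidationError("persistence_prob outside [0,1]")
        if not 0.0 <= self.communal_tp_detect_prob <= 1.0:
            raise ValidationError("communal_tp_detect_prob outside [0,1]")
        for frac in (
            self.frac_taxonomy,
            self.frac_lysogenic,
            self.frac_known_lytic,
            self.frac_circular,
            self.frac_clustered,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("catalogue fractions must lie in [0,1]")
        if self.frac_lysogenic + self.frac_known_lytic > 1.0:
            raise ValidationError("lifecycle fractions exceed 1")
        needed = self.communal_pool_size + sum(
            self.n_subjects[c]
            * (self.ppv_size.get(c, 0) + 3 * self.transient_per_timepoint.get(c, 0))
            for c in self.n_subjects
        )
        if needed > self.catalog_size:
            raise ValidationError(
                f"catalog_size={self.catalog_size} too small for the requested "
                f"community structure (needs >= {needed}); enlarge the catalogue "
                "or shrink PPV/transient sizes"
            )
        if self.reads_per_sample < 1:
            raise ValidationError("reads_per_sample must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SimulationConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValidationError(f"unknown simulation config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, Mapping):
                current = {**current, **value}
                setattr(cfg, key, current)
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg


def _required_pvogs(length: int) -> int:
    for upper, needed in PVOG_THRESHOLDS:
        if length < upper:
            return needed
    raise AssertionError  # pragma: no cover


def generate_catalog(
    config: SimulationConfig, seed: int = 0
) -> list[VirusRecord]:
    """Generate a virus catalogue with study-like marginals.

    Lengths are log-uniform over [min_length, max_length); the majority of
    records are unclassified, with tailed-phage families dominating the
    assigned minority; pVOG hit counts always pass the length-class
    threshold (these are contigs that survived screening).
    """
    config.validate()
    if config.catalog_size == 0:
        raise ValidationError("catalog_size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    n = config.catalog_size
    lengths = np.exp(
        rng.uniform(np.log(config.min_length), np.log(config.max_length), size=n)
    ).astype(int)
    lengths = np.clip(lengths, config.min_length, config.max_length)
    fams = list(FAMILY_WEIGHTS)
    weights = np.array([FAMILY_WEIGHTS[f] for f in fams])
    weights = weights / weights.sum()
    has_tax = rng.random(n) < config.frac_taxonomy
    fam_draw = rng.choice(len(fams), size=n, p=weights)
    u_life = rng.random(n)
    circ = rng.random(n) < config.frac_circular
    clustered = rng.random(n) < config.frac_clustered

    records: list[VirusRecord] = []
    width = len(str(n))
    cluster_counter = 0
    cluster_slot = 0
    cluster_cur: str | None = None
    for i in range(n):
        family = fams[fam_draw[i]] if has_tax[i] else "unknown"
        vclass = (
            "Caudoviricetes"
            if family in _TAILED
            else ("unknown" if family == "unknown" else family)
        )
        if u_life[i] < config.frac_lysogenic:
            lysogenic: bool | None = True
        elif u_life[i] < config.frac_lysogenic + config.frac_known_lytic:
            lysogenic = False
        else:
            lysogenic = None
        if clustered[i]:
            if cluster_cur is None or cluster_slot >= 3:
                cluster_counter += 1
                cluster_cur = f"VC_{cluster_counter:05d}"
                cluster_slot = 0
            cluster_id = cluster_cur
            cluster_slot += 1
        else:
            cluster_id = None
        length = int(lengths[i])
        records.append(
            VirusRecord(
                virus_id=f"vir_{i + 1:0{width}d}",
                length=length,
                circular=bool(circ[i]),
                family=family,
                viral_class=vclass,
                lysogenic=lysogenic,
                cluster_id=cluster_id,
                pvog_hits=int(_required_pvogs(length) + rng.poisson(3.0)),
            )
        )
    return records


def generate_design(config: SimulationConfig, seed: int = 0) -> CohortDesign:
    """Generate subjects, conditions, time points and collection days."""
    config.validate()
    samples: list[SampleRecord] = []
    for cond in ("Control", "CD", "UC"):
        n = config.n_subjects.get(cond, 0)
        n_two = config.n_two_timepoint.get(cond, 0)
        for i in range(n):
            subj = f"{cond}_{i + 1:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(1, _cond_key(cond), i))
            )
            n_tp = 2 if i >= n - n_two else 3
            day = 0
            for tp in range(1, n_tp + 1):
                if tp > 1:
                    gap = max(
                        30,
                        int(
                            round(
                                rng.normal(
                                    config.interval_mean_days,
                                    config.interval_sd_days,
                                )
                            )
                        ),
                    )
                    day += gap
                samples.append(
                    SampleRecord(
                        sample_id=f"{subj}_T{tp}",
                        subject_id=subj,
                        condition=cond,
                        timepoint=tp,
                        collection_day=day,
                    )
                )
    return CohortDesign(samples)


def _cond_key(cond: str) -> int:
    return {"Control": 0, "CD": 1, "UC": 2}[cond]


@dataclass
class SimulationResult:
    """Everything one simulated cohort produced, plus its ground truth."""

    config: SimulationConfig
    seed: int
    catalog: list[VirusRecord]
    design: CohortDesign
    counts: AbundanceMatrix
    presence_truth: pd.DataFrame  # virus x sample boolean
    truth: pd.DataFrame  # per (virus, subject): membership class
    evidence: list[CoverageEvidence]


def generate_cohort(
    config: SimulationConfig,
    catalog: Sequence[VirusRecord],
    seed: int = 0,
    with_evidence: bool = True,
) -> SimulationResult:
    """Generate the cohort: design, intended presence, counts and evidence.

    The catalogue is partitioned into a communal pool (first
    ``communal_pool_size`` records) and disjoint private blocks per subject
    from which PPV and transient viruses are drawn, so inter-subject sharing
    arises only through the communal pool.
    """
    config.validate()
    design = generate_design(config, seed)
    virus_ids = [r.virus_id for r in catalog]
    lysogenic = np.array([r.lysogenic is True for r in catalog])
    lengths = np.array([r.length for r in catalog])
    n_virus = len(catalog)
    communal_idx = np.arange(min(config.communal_pool_size, n_virus))

    sample_ids = design.sample_ids
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    presence = np.zeros((n_virus, len(sample_ids)), dtype=bool)
    log_weight = np.full((n_virus, len(sample_ids)), -np.inf)

    truth_rows = []
    next_private = len(communal_idx)
    # canonical Control -> CD -> UC order with per-condition subject index:
    # private blocks are allocated sequentially, so appending subjects to a
    # condition never moves the blocks of subjects generated before them
    by_cond = design.subjects_by_condition()
    ordered = [
        (cond, i, subj)
        for cond in ("Control", "CD", "UC")
        for i, subj in enumerate(by_cond.get(cond, []))
    ]
    for cond, i_subj, subj in ordered:
        recs = design.by_subject[subj]
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(2, _cond_key(cond), i_subj))
        )
        n_tp = len(recs)
        cols = [sample_pos[r.sample_id] for r in recs]

        block = config.ppv_size.get(cond, 0) + 3 * config.transient_per_timepoint.get(
            cond, 0
        )
        private = np.arange(next_private, min(next_private + block, n_virus))
        next_private += block

        carried = communal_idx[
            rng.random(len(communal_idx)) < config.communal_carriage.get(cond, 0.0)
        ]
        ppv = private[: config.ppv_size.get(cond, 0)]
        trans_pool = private[config.ppv_size.get(cond, 0) :]
        n_trans = config.transient_per_timepoint.get(cond, 0)

        subject_virus_idx: list[int] = []
        for v in carried:
            truth_rows.append(
                {"virus_id": virus_ids[v], "subject_id": subj, "class": "communal"}
            )
            for c in cols:
                if rng.random() < config.communal_tp_detect_prob:
                    presence[v, c] = True
            subject_virus_idx.append(v)
        for v in ppv:
            truth_rows.append(
                {"virus_id": virus_ids[v], "subject_id": subj, "class": "ppv"}
            )
            for t, c in enumerate(cols):
                if rng.random() < config.persistence_prob:
                    presence[v, c] = True
            subject_virus_idx.append(v)
        # transients: a fresh slice of the private pool per time point
        for t, c in enumerate(cols):
            chunk = trans_pool[t * n_trans : (t + 1) * n_trans]
            for v in chunk:
                truth_rows.append(
                    {
                        "virus_id": virus_ids[v],
                        "subject_id": subj,
                        "class": "transient",
                    }
                )
                presence[v, c] = True
                subject_virus_idx.append(v)

        # heavy-tailed abundances: lognormal base per virus-subject plus
        # per-time-point multiplicative noise; lysogens boosted in IBD
        for v in set(subject_virus_idx):
            base = rng.normal(0.0, config.abundance_sigma_between)
            if cond in ("CD", "UC") and lysogenic[v]:
                base += config.lysogen_ibd_log_boost
            for c in cols:
                if presence[v, c]:
                    log_weight[v, c] = base + rng.normal(
                        0.0, config.abundance_sigma_within
                    )

    # counts: multinomial reads over present viruses, per sample
    counts = np.zeros((n_virus, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(3, j))
        )
        lw = log_weight[:, j]
        present = np.isfinite(lw)
        if not present.any():
            continue
        w = np.exp(lw[present] - lw[present].max())
        p = w / w.sum()
        counts[present, j] = rng.multinomial(config.reads_per_sample, p)

    counts_df = pd.DataFrame(counts, index=virus_ids, columns=sample_ids)
    presence_df = pd.DataFrame(presence, index=virus_ids, columns=sample_ids)
    truth = pd.DataFrame(truth_rows)

    evidence: list[CoverageEvidence] = []
    if with_evidence:
        evidence = _evidence_from_counts(
            config, lengths, virus_ids, sample_ids, counts, seed
        )
    return SimulationResult(
        config=config,
        seed=seed,
        catalog=list(catalog),
        design=design,
        counts=AbundanceMatrix(counts_df),
        presence_truth=presence_df,
        truth=truth,
        evidence=evidence,
    )


def _union_breadth(
    starts: np.ndarray, read_len: int, contig_len: int
) -> float:
    """Breadth of coverage of fixed-length reads from sorted integer starts."""
    if starts.size == 0:
        return 0.0
    s = np.sort(starts)
    gaps = np.diff(s)
    covered = np.minimum(gaps, read_len).sum() + read_len
    return float(min(covered, contig_len) / contig_len)


def _evidence_from_counts(
    config: SimulationConfig,
    lengths: np.ndarray,
    virus_ids: Sequence[str],
    sample_ids: Sequence[str],
    counts: np.ndarray,
    seed: int,
) -> list[CoverageEvidence]:
    evidence = []
    for j, sid in enumerate(sample_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(4, j))
        )
        nz = np.flatnonzero(counts[:, j])
        for v in nz:
            n_reads = int(counts[v, j])
            contig_len = int(lengths[v])
            read_len = min(config.read_length, contig_len)
            starts = rng.integers(0, contig_len - read_len + 1, size=n_reads)
            evidence.append(
                CoverageEvidence(
                    virus_id=virus_ids[v],
                    sample_id=sid,
                    mapped_reads=n_reads,
                    breadth=_union_breadth(starts, read_len, contig_len),
                )
            )
    return evidence


def generate_depth_evidence(
    config: SimulationConfig,
    catalog: Sequence[VirusRecord],
    counts: AbundanceMatrix,
    seed: int = 0,
) -> tuple[list[CoverageEvidence], dict[tuple[str, str], np.ndarray]]:
    """Per-cell evidence with explicit per-base depth vectors.

    Reads of ``read_length`` bp are placed uniformly along each contig (reads
    longer than the contig are truncated to it, logged via the read-length
    clamp); the depth vector and the breadth derived from it are returned for
    every nonzero (virus, sample) cell.  Meant for desk-scale matrices — the
    vectors are dense.
    """
    lengths = {r.virus_id: r.length for r in catalog}
    evidence: list[CoverageEvidence] = []
    depths: dict[tuple[str, str], np.ndarray] = {}
    arr = counts.counts.to_numpy()
    virus_ids = counts.virus_ids
    for j, sid in enumerate(counts.sample_ids):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4, j)))
        nz = np.flatnonzero(arr[:, j])
        for v in nz:
            vid = virus_ids[v]
            contig_len = int(lengths[vid])
            read_len = min(config.read_length, contig_len)
            n_reads = int(arr[v, j])
            starts = rng.integers(0, contig_len - read_len + 1, size=n_reads)
            # difference-array coverage accumulation
            diff = np.zeros(contig_len + 1, dtype=np.int64)
            np.add.at(diff, starts, 1)
            np.add.at(diff, starts + read_len, -1)
            depth = np.cumsum(diff[:-1])
            depths[(vid, sid)] = depth
            evidence.append(
                CoverageEvidence(
                    virus_id=vid,
                    sample_id=sid,
                    mapped_reads=n_reads,
                    breadth=float(np.count_nonzero(depth) / contig_len),
                )
            )
    return evidence, depths


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
    with_evidence: bool = True,
) -> SimulationResult:
    """Convenience wrapper: catalogue + cohort in one call."""
    if config is None:
        config = SimulationConfig()
    catalog = generate_catalog(config, seed)
    return generate_cohort(config, catalog, seed, with_evidence=with_evidence)


def write_simulation(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write catalogue, metadata, counts, evidence and ground truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": out / "catalog.tsv",
        "metadata": out / "metadata.csv",
        "counts": out / "counts.tsv",
        "evidence": out / "evidence.tsv",
        "truth": out / "ground_truth.tsv",
    }
    write_catalog(result.catalog, paths["catalog"])
    write_metadata(result.design, paths["metadata"])
    write_counts_matrix(result.counts, paths["counts"])
    write_evidence_table(result.evidence, paths["evidence"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
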