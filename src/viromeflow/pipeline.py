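"""Stage orchestration: each stage reads/writes tidy tables in an output dir.

The CLI wraps these functions; tests and scripts call them directly.  No
stage mutates its inputs; outputs land only under the stage's output
directory, and a run manifest records the seed, a config hash and sha256
checksums of every file written so reruns can be compared.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from viromeflow import communal as communal_mod
from viromeflow import detection as detection_mod
from viromeflow import diversity as diversity_mod
from viromeflow import temporal as temporal_mod
from viromeflow.contig_screen import read_pairwise_hits, screen_catalog
from viromeflow.io_formats import (
    AbundanceMatrix,
    CohortDesign,
    read_catalog,
    read_counts_matrix,
    read_metadata,
    reconcile,
    write_catalog,
    write_counts_matrix,
)
from viromeflow.simulate import SimulationConfig, simulate_cohort, write_simulation

_FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    stage: str,
    seed: int | None,
    config: Mapping | None,
    inputs: Sequence[Path],
    outputs: Sequence[Path],
) -> Path:
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        if config is not None
        else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {Path(p).name: _sha256(Path(p)) for p in outputs},
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig()
    result = simulate_cohort(config, seed=seed)
    paths = write_simulation(result, out)
    write_manifest(
        out, "simulate", seed, json.loads(json.dumps(config.__dict__, default=str)),
        [], list(paths.values()),
    )
    return paths


def run_screen(
    catalog_path: str | Path,
    out_dir: str | Path,
    hits_path: str | Path | None = None,
    min_len: int = 1000,
    id_thresh: float = 90.0,
    cov_thresh: float = 90.0,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_catalog(catalog_path)
    hits = []
    if hits_path is not None:
        hits = read_pairwise_hits(
            hits_path, {r.virus_id: r.length for r in records}
        )
    retained, discarded = screen_catalog(
        records, hits, min_len, id_thresh, cov_thresh
    )
    cat_out = out / "screened_catalog.tsv"
    write_catalog(retained, cat_out)
    disc_out = _write(
        pd.DataFrame(
            {
                "discarded_id": list(discarded),
                "retained_id": [discarded[k] for k in discarded],
            }
        ),
        out / "discarded_map.tsv",
    )
    inputs = [Path(catalog_path)] + ([Path(hits_path)] if hits_path else [])
    write_manifest(out, "screen", None, None, inputs, [cat_out, disc_out])
    return {"catalog": cat_out, "discarded": disc_out}


def run_detect(
    catalog_path: str | Path,
    evidence_path: str | Path,
    counts_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    strict: bool = True,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = read_catalog(catalog_path)
    counts = read_counts_matrix(counts_path)
    design = read_metadata(metadata_path)
    counts, design = reconcile(counts, design, strict=strict)
    evidence = detection_mod.read_evidence_table(evidence_path)
    evidence = [e for e in evidence if e.sample_id in set(counts.sample_ids)]
    presence = detection_mod.build_presence(evidence, catalog, counts.sample_ids)
    masked = detection_mod.mask_counts(counts, presence)
    pres_out = out / "presence.tsv"
    presence.astype(int).to_csv(pres_out, sep="\t", index_label="virus_id")
    masked_out = out / "masked_counts.tsv"
    write_counts_matrix(masked, masked_out)
    write_manifest(
        out,
        "detect",
        None,
        {"strict": strict},
        [Path(catalog_path), Path(evidence_path), Path(counts_path), Path(metadata_path)],
        [pres_out, masked_out],
    )
    return {"presence": pres_out, "masked_counts": masked_out}


def _load_presence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def run_diversity(
    counts_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    metric: str = "canberra",
    permutations: int = 999,
    rarefaction_reps: int = 100,
    seed: int = 0,
    pool_ibd: bool = True,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_counts_matrix(counts_path)
    design = read_metadata(metadata_path)
    counts, design = reconcile(counts, design, strict=False)

    alpha = diversity_mod.alpha_table(
        counts, reps=rarefaction_reps, seed=np.random.default_rng(seed)
    )
    rel = counts.relative_abundance()
    dm = diversity_mod.distance_matrix(rel, metric)
    ordination = diversity_mod.pcoa(dm)
    cond_of = {s: design.condition_of_sample(s) for s in rel.columns}
    groups = (
        {s: ("Control" if c == "Control" else "IBD") for s, c in cond_of.items()}
        if pool_ibd
        else cond_of
    )
    perm = diversity_mod.permanova(
        dm, [cond_of[s] for s in dm.ids], n_perm=permutations, seed=seed + 1
    )
    cents = diversity_mod.centroids_and_extremes(
        ordination, alpha["shannon"], groups
    )
    rho, p = diversity_mod.alpha_condition_correlation(
        alpha["shannon"].reindex(rel.columns),
        [cond_of[s] for s in rel.columns],
    )

    paths = {}
    paths["alpha"] = _write(
        alpha.rename_axis("sample_id").reset_index(), out / "alpha.tsv"
    )
    paths["distance"] = out / "distance.tsv"
    dm.to_frame().to_csv(paths["distance"], sep="\t", index_label="sample_id",
                         float_format=_FLOAT_FMT)
    coords = ordination.coordinates.iloc[:, : min(10, ordination.coordinates.shape[1])]
    paths["pcoa"] = _write(
        coords.rename_axis("sample_id").reset_index(), out / "pcoa_coordinates.tsv"
    )
    paths["eigenvalues"] = _write(
        pd.DataFrame(
            {
                "axis": np.arange(1, len(ordination.eigenvalues) + 1),
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": ordination.proportion_explained,
            }
        ),
        out / "pcoa_eigenvalues.tsv",
    )
    paths["stats"] = _write(
        pd.DataFrame(
            [
                {
                    "test": "permanova",
                    "metric": metric,
                    "statistic": perm.pseudo_F,
                    "r_squared": perm.r_squared,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                },
                {
                    "test": "spearman_alpha_condition",
                    "metric": "shannon",
                    "statistic": rho,
                    "r_squared": np.nan,
                    "p_value": p,
                    "n_permutations": np.nan,
                },
            ]
        ),
        out / "diversity_stats.tsv",
    )
    paths["centroids"] = _write(
        cents.rename_axis("group").reset_index(), out / "centroids.tsv"
    )
    write_manifest(
        out,
        "diversity",
        seed,
        {"metric": metric, "permutations": permutations},
        [Path(counts_path), Path(metadata_path)],
        list(paths.values()),
    )
    return paths


def run_communal(
    counts_path: str | Path,
    presence_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    catalog_path: str | Path | None = None,
    n_subjects: int = 10,
    reps: int = 20,
    seed: int = 0,
    subset: str = "all",
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_counts_matrix(counts_path)
    design = read_metadata(metadata_path)
    counts, design = reconcile(counts, design, strict=False)
    presence = _load_presence(presence_path)[counts.sample_ids]
    catalog = read_catalog(catalog_path) if catalog_path else None

    subj_pres = communal_mod.subject_presence(presence, design, mode="union")
    profile = communal_mod.communal_set(subj_pres)
    spectrum = communal_mod.bootstrap_sharing(
        presence,
        design,
        list(profile.index[profile["is_communal"]]),
        n_subjects=n_subjects,
        reps=reps,
        seed=seed,
    )
    rel = counts.relative_abundance()
    strata = communal_mod.strata_abundance(
        rel, profile, design, subset=subset, catalog=catalog
    )

    paths = {}
    paths["profile"] = _write(
        profile.rename_axis("virus_id").reset_index(), out / "sharing_profile.tsv"
    )
    paths["spectrum"] = _write(spectrum, out / "sharing_spectrum.tsv")
    paths["strata"] = _write(strata, out / "sharing_strata.tsv")
    inputs = [Path(counts_path), Path(presence_path), Path(metadata_path)]
    if catalog_path:
        inputs.append(Path(catalog_path))
    write_manifest(
        out,
        "communal",
        seed,
        {"n_subjects": n_subjects, "reps": reps, "subset": subset},
        inputs,
        list(paths.values()),
    )
    return paths


def run_temporal(
    counts_path: str | Path,
    presence_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    metric: str = "bray_curtis",
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_counts_matrix(counts_path)
    design = read_metadata(metadata_path)
    counts, design = reconcile(counts, design, strict=False)
    presence = _load_presence(presence_path)[counts.sample_ids]
    rel = counts.relative_abundance()

    persistence = temporal_mod.persistence_classes(presence, design)
    richness = temporal_mod.richness_by_condition(presence, design)
    ternary_frames = []
    for subj in design.subject_ids:
        if len(design.by_subject[subj]) == 3 and all(
            r.sample_id in rel.columns for r in design.by_subject[subj]
        ):
            ternary_frames.append(temporal_mod.ternary_coords(rel, design, subj))
    ternary = (
        pd.concat(ternary_frames, ignore_index=True)
        if ternary_frames
        else pd.DataFrame(columns=["virus_id", "subject_id", "condition", "p1", "p2", "p3"])
    )
    dis = temporal_mod.intra_inter_dissimilarity(rel, design, metric=metric)

    paths = {}
    paths["persistence"] = _write(persistence, out / "persistence.tsv")
    paths["richness"] = _write(richness, out / "richness.tsv")
    paths["ternary"] = _write(ternary, out / "ternary.tsv")
    paths["dissimilarity"] = _write(dis.pairs, out / "dissimilarity_pairs.tsv")
    paths["dissimilarity_test"] = _write(
        pd.DataFrame(
            [
                {
                    "test": "wilcoxon_rank_sum_intra_vs_inter",
                    "metric": metric,
                    "statistic": dis.statistic,
                    "p_value": dis.p_value,
                    "n_intra": len(dis.intra),
                    "n_inter": len(dis.inter),
                }
            ]
        ),
        out / "dissimilarity_test.tsv",
    )
    write_manifest(
        out,
        "temporal",
        None,
        {"metric": metric},
        [Path(counts_path), Path(presence_path), Path(metadata_path)],
        list(paths.values()),
    )
    return paths


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    config: SimulationConfig | None = None,
    metric: str = "canberra",
    permutations: int = 999,
    bootstrap_reps: int = 20,
    bootstrap_subjects: int = 10,
) -> dict[str, Path]:
    """simulate -> detect -> diversity -> communal -> temporal, chained."""
    out = Path(out_dir)
    sim = run_simulate(out / "simulate", seed=seed, config=config)
    det = run_detect(
        sim["catalog"], sim["evidence"], sim["counts"], sim["metadata"],
        out / "detect",
    )
    div = run_diversity(
        det["masked_counts"], sim["metadata"], out / "diversity",
        metric=metric, permutations=permutations, seed=seed,
    )
    com = run_communal(
        det["masked_counts"], det["presence"], sim["metadata"], out / "communal",
        catalog_path=sim["catalog"], reps=bootstrap_reps,
        n_subjects=bootstrap_subjects, seed=seed,
    )
    tem = run_temporal(
        det["masked_counts"], det["presence"], sim["metadata"], out / "temporal",
    )
    all_paths = {}
    for prefix, d in (
        ("simulate", sim), ("detect", det), ("diversity", div),
        ("communal", com), ("temporal", tem),
    ):
        for k, v in d.items():
            all_paths[f"{prefix}.{k}"] = Path(v)
    return all_paths
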