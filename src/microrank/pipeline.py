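"""Stage orchestration: simulate -> rank -> score -> meta -> intervention.

``run_pipeline`` executes the configured stages in dependency order,
derives every stage's randomness from one master seed via named
substreams (so reordering stages cannot change results), writes
plain-text TSV/JSON artifacts, and records a manifest with config
snapshot, input digests, package versions and per-stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .meta import beta_to_smd, fit_group_effect, paule_mandel
from .profiles import (
    prevalence_filter,
    read_merged_profiles,
    read_metadata,
    write_merged_profiles,
    write_metadata,
)
from .ranking import (
    build_ranking,
    correlate_all,
    marker_percentiles,
    read_ranking,
    write_ranking,
)
from .scoring import score_samples
from .simulate import (
    default_marker_panel,
    generate_case_control_collection,
    generate_multi_cohort,
    standard_multi_cohort_configs,
)
from .intervention import prepost_differential, rank_shift_enrichment

__all__ = ["run_pipeline", "stage_seed", "KNOWN_STAGES"]

KNOWN_STAGES = ("simulate", "rank", "score", "meta", "intervention")


def stage_seed(master_seed: int, stage: str) -> int:
    """Named substream derivation: stable under stage reordering."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: dict, out: Path, seed: int) -> list[Path]:
    n_cohorts = int(cfg.get("n_cohorts", 3))
    overrides = {
        k: cfg[k]
        for k in ("n_samples", "n_sgbs", "n_favourable", "n_unfavourable",
                  "effect_size", "marker_noise_sd")
        if k in cfg
    }
    configs = standard_multi_cohort_configs(seed, n_cohorts, **overrides)
    cohorts, truth = generate_multi_cohort(configs)
    outputs = []
    markers_all = []
    meta_all = []
    for cohort_id, (table, meta, markers) in cohorts.items():
        p = out / f"profiles_{cohort_id}.tsv"
        write_merged_profiles(table, p)
        outputs.append(p)
        meta_all.append(meta)
        m = markers.copy()
        m.insert(0, "cohort_id", cohort_id)
        markers_all.append(m)
    meta_path = out / "metadata.tsv"
    write_metadata(pd.concat(meta_all), meta_path)
    markers_path = out / "markers.tsv"
    pd.concat(markers_all).to_csv(markers_path, sep="\t", float_format="%.10g")
    truth_path = out / "planted_truth.tsv"
    truth.as_series().to_csv(truth_path, sep="\t")
    panel_path = out / "marker_panel.tsv"
    default_marker_panel().frame.to_csv(panel_path, sep="\t", index=False)
    return outputs + [meta_path, markers_path, truth_path, panel_path]


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise ValidationError(f"missing upstream artifact(s): {missing}")


def _stage_rank(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .ranking import MarkerPanel

    _require(out, "marker_panel.tsv", "metadata.tsv", "markers.tsv")
    panel = MarkerPanel(pd.read_csv(out / "marker_panel.tsv", sep="\t"))
    meta = read_metadata(out / "metadata.tsv")
    markers = pd.read_csv(out / "markers.tsv", sep="\t", index_col="sample_id")
    prevalence = float(cfg.get("prevalence", 0.2))
    covariate_names = list(cfg.get("covariates", ["sex", "age", "bmi"]))
    min_cohorts = int(cfg.get("min_cohorts", 2))
    percentiles = {}
    for cohort_id, sub in meta.groupby("cohort_id"):
        prof_path = out / f"profiles_{cohort_id}.tsv"
        if not prof_path.exists():
            raise ValidationError(f"missing upstream artifact: {prof_path.name}")
        table = read_merged_profiles(prof_path)
        table = prevalence_filter(table.subset_samples(sub.index), prevalence)
        frame = correlate_all(
            table,
            markers.loc[sub.index, [c for c in markers.columns if c != "cohort_id"]],
            sub[covariate_names],
        )
        percentiles[cohort_id] = marker_percentiles(frame, panel)
    ranking = build_ranking(percentiles, panel, min_cohorts=min_cohorts)
    path = out / "ranking.tsv"
    write_ranking(ranking, path)
    return [path]


def _stage_score(cfg: dict, out: Path, seed: int) -> list[Path]:
    _require(out, "ranking.tsv", "metadata.tsv")
    ranking = read_ranking(out / "ranking.tsv")
    meta = read_metadata(out / "metadata.tsv")
    k = int(cfg.get("k", 50))
    reports = []
    for cohort_id in sorted(meta["cohort_id"].unique()):
        prof_path = out / f"profiles_{cohort_id}.tsv"
        if not prof_path.exists():
            raise ValidationError(f"missing upstream artifact: {prof_path.name}")
        table = read_merged_profiles(prof_path)
        rep = score_samples(table, ranking, k=k)
        rep.insert(0, "cohort_id", cohort_id)
        reports.append(rep)
    path = out / "scores.tsv"
    pd.concat(reports).to_csv(path, sep="\t", float_format="%.10g")
    return [path]


def _stage_meta(cfg: dict, out: Path, seed: int) -> list[Path]:
    _require(out, "ranking.tsv", "planted_truth.tsv")
    ranking = read_ranking(out / "ranking.tsv")
    truth_path = out / "planted_truth.tsv"
    if truth_path.exists():
        truth_series = pd.read_csv(truth_path, sep="\t", index_col=0)["direction"]
    else:
        raise ValidationError("missing upstream artifact: planted_truth.tsv")
    from .simulate import PlantedTruth

    truth = PlantedTruth(
        direction={str(k): int(v) for k, v in truth_series.items()},
        effect_size=float(cfg.get("effect_size", 0.4)),
    )
    datasets, _ = generate_case_control_collection(
        n_datasets=int(cfg.get("n_datasets", 5)),
        n_per_arm=int(cfg.get("n_per_arm", 60)),
        truth=truth,
        case_shift=float(cfg.get("case_shift", 0.5)),
        seed=seed,
    )
    k = int(cfg.get("k", 50))
    estimates = []
    for table, meta_df in datasets:
        rep = score_samples(table, ranking, k=k)
        est = fit_group_effect(
            rep["rank_sum"].to_numpy(),
            (meta_df["status"] == "case").astype(int).to_numpy(),
            meta_df[["sex", "age", "bmi"]],
            dataset_id=meta_df["cohort_id"].iloc[0],
        )
        estimates.append(beta_to_smd(est))
    pooled = paule_mandel(
        [e.smd for e in estimates], [e.smd_se**2 for e in estimates]
    )
    path = out / "meta.json"
    payload = {
        "per_study": [
            {
                "dataset_id": e.dataset_id,
                "beta": e.beta,
                "smd": e.smd,
                "smd_se": e.smd_se,
                "n_control": e.n_control,
                "n_case": e.n_case,
            }
            for e in estimates
        ],
        "pooled": {
            "smd": pooled.pooled,
            "se": pooled.se,
            "ci95": list(pooled.ci95),
            "tau2": pooled.tau2,
            "p": pooled.p,
            "method": pooled.method,
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return [path]


def _stage_intervention(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .simulate import PlantedTruth, generate_paired_intervention

    _require(out, "ranking.tsv", "planted_truth.tsv")

    truth_series = pd.read_csv(out / "planted_truth.tsv", sep="\t", index_col=0)[
        "direction"
    ]
    truth = PlantedTruth(
        direction={str(k): int(v) for k, v in truth_series.items()},
        effect_size=float(cfg.get("effect_size", 0.4)),
    )
    n_up = int(cfg.get("n_response", 10))
    n_down = int(cfg.get("n_decrease", n_up))
    baseline, endpoint, _ = generate_paired_intervention(
        n_subjects=int(cfg.get("n_subjects", 100)),
        truth=truth,
        response_set=truth.favourable[:n_up],
        decrease_set=truth.unfavourable[:n_down],
        shift=float(cfg.get("shift", np.log(2.0))),
        seed=seed,
    )
    records = prepost_differential(baseline, endpoint)
    path = out / "intervention.tsv"
    records.to_csv(path, sep="\t", float_format="%.10g")
    ranking = read_ranking(out / "ranking.tsv")
    enr = rank_shift_enrichment(records, ranking,
                                q_threshold=float(cfg.get("q", 0.05)))
    enr_path = out / "enrichment.json"
    enr_path.write_text(
        json.dumps(
            {
                "u_statistic": enr.u_statistic,
                "p": enr.p,
                "median_increase": enr.median_increase,
                "median_decrease": enr.median_decrease,
                "n_increase": enr.n_increase,
                "n_decrease": enr.n_decrease,
                "n_unranked": enr.n_unranked,
                "note": enr.note,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [path, enr_path]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "rank": _stage_rank,
    "score": _stage_score,
    "meta": _stage_meta,
    "intervention": _stage_intervention,
}


def run_pipeline(config: dict, out_dir, seed: int) -> dict:
    """Run the configured stages; return (and write) the manifest.

    ``config`` maps stage names (subset of :data:`KNOWN_STAGES`) to their
    per-stage option dicts.  Stages always execute in canonical
    dependency order regardless of mapping order.
    """
    unknown = set(config) - set(KNOWN_STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s) in config: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": int(seed),
        "config": config,
        "versions": {"microrank": __version__},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for stage in KNOWN_STAGES:
        if stage not in config:
            continue
        runner = _STAGE_RUNNERS[stage]
        outputs = runner(config[stage] or {}, out, stage_seed(seed, stage))
        manifest["stages"][stage] = {
            "outputs": [p.name for p in outputs],
            "digests": {p.name: _digest(p) for p in outputs},
            "seed": stage_seed(seed, stage),
        }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
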