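"""Synthetic multi-cohort microbiome collections with planted ground truth.

The generators emulate the structure of multi-cohort SGB-level taxonomic
profiles: zero-inflated, compositional relative abundances; per-sample
sex/age/BMI covariates; a panel of health and diet markers; case-control
collections; and paired pre/post intervention designs.  A set of planted
"favourable" and "unfavourable" species drives the markers, so that every
downstream stage (ranking, scoring, meta-analysis, intervention) can be
validated against a known truth without any real data.

Abundance model: per-SGB Bernoulli presence x log-normal abundance,
renormalized per sample to a random total in [0.85, 1.0] to mimic the
unclassified remainder.  Markers are direction-consistent linear
combinations of *rank-transformed* planted-SGB abundances plus covariate
effects and Gaussian noise, so the planted signal is exactly the quantity
a partial Spearman correlation estimates.

All generators are pure functions of their configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .profiles import AbundanceTable
from .ranking import MarkerPanel

__all__ = [
    "PlantedTruth",
    "CohortSimConfig",
    "default_marker_panel",
    "make_planted_truth",
    "generate_cohort",
    "generate_multi_cohort",
    "standard_multi_cohort_configs",
    "generate_case_control_collection",
    "generate_paired_intervention",
]


def default_marker_panel() -> MarkerPanel:
    """A 13-marker panel spanning the four categories with mixed directions.

    Synthetic stand-ins for the kinds of markers used in practice:
    anthropometric/personal measures, fasting lipids and inflammation,
    postprandial responses, and diet-quality indices.
    """
    records = [
        ("ascvd_risk", "personal", -1),
        ("blood_pressure", "personal", -1),
        ("visceral_fat", "personal", -1),
        ("hdl", "fasting", +1),
        ("triglycerides", "fasting", -1),
        ("glyca", "fasting", -1),
        ("fasting_glucose", "fasting", -1),
        ("pp_glucose_iauc", "postprandial", -1),
        ("pp_triglycerides", "postprandial", -1),
        ("pp_insulin", "postprandial", -1),
        ("hei", "dietary", +1),
        ("hpdi", "dietary", +1),
        ("hfd", "dietary", +1),
    ]
    return MarkerPanel.from_records(records)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth species effects shared by all cohorts of a collection.

    ``direction`` maps sgb_id -> {+1 favourable, -1 unfavourable, 0 null};
    ``effect_size`` is the standardized marker shift per unit of
    rank-transformed abundance for the planted species.
    """

    direction: dict[str, int]
    effect_size: float

    def __post_init__(self) -> None:
        bad = {d for d in self.direction.values()} - {-1, 0, 1}
        if bad:
            raise ValidationError(f"directions must be in {{-1,0,+1}}, got {bad}")

    @property
    def favourable(self) -> list[str]:
        return sorted(s for s, d in self.direction.items() if d == 1)

    @property
    def unfavourable(self) -> list[str]:
        return sorted(s for s, d in self.direction.items() if d == -1)

    @property
    def sgb_ids(self) -> list[str]:
        return sorted(self.direction)

    def as_series(self) -> pd.Series:
        return pd.Series(self.direction, name="direction").sort_index()


@dataclass
class CohortSimConfig:
    """Configuration of one simulated cohort.

    Defaults define the standard study conditions used throughout the
    test-bed: 500 samples, 200 SGBs of which 20 favourable and 20
    unfavourable with effect 0.4, presence probabilities in [0.25, 0.9]
    (all planted SGBs comfortably above a 20% prevalence filter),
    log-normal within-SGB spread of 1.0, and unit marker noise.
    """

    n_samples: int = 500
    n_sgbs: int = 200
    n_favourable: int = 20
    n_unfavourable: int = 20
    effect_size: float = 0.4
    zero_inflation: tuple[float, float] = (0.25, 0.9)
    log_abundance_sd: float = 1.0
    marker_panel: MarkerPanel = field(default_factory=default_marker_panel)
    marker_noise_sd: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.3, "age": 0.3, "bmi": 0.4}
    )
    cohort_shift: float = 0.0
    confound_bmi: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_sgbs) <= 0:
            raise ValidationError("counts must be positive")
        if self.n_favourable + self.n_unfavourable > self.n_sgbs:
            raise ValidationError("planted sets exceed the SGB universe")
        lo, hi = self.zero_inflation
        if not (0 < lo <= hi <= 1):
            raise ValidationError("zero_inflation range must lie in (0, 1]")


def make_planted_truth(config: CohortSimConfig) -> PlantedTruth:
    """Planted truth implied by a config: first SGBs favourable, next
    unfavourable, rest null.  Deterministic by construction."""
    ids = [f"SGB{i + 1:04d}" for i in range(config.n_sgbs)]
    direction = {s: 0 for s in ids}
    for s in ids[: config.n_favourable]:
        direction[s] = 1
    for s in ids[config.n_favourable: config.n_favourable + config.n_unfavourable]:
        direction[s] = -1
    return PlantedTruth(direction=direction, effect_size=config.effect_size)


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    sex = rng.integers(0, 2, size=n)
    age = np.clip(rng.normal(50, 13, size=n), 18, 85)
    bmi = np.clip(rng.normal(26, 4.2, size=n), 18.5, 45)
    return pd.DataFrame({"sex": sex, "age": age, "bmi": bmi})


def _abundances(
    rng: np.random.Generator,
    n: int,
    truth: PlantedTruth,
    config: CohortSimConfig,
    presence_logit_shift: np.ndarray | None = None,
    log_mean_shift: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-inflated log-normal abundance matrix closed to sum <= 1.

    Optional per-(sample, SGB) shifts act on the presence logit and on the
    log-normal mean (used by the case-control and confounded generators).
    """
    ids = truth.sgb_ids
    m = len(ids)
    lo, hi = config.zero_inflation
    # Per-SGB structural parameters are drawn from a dedicated substream so
    # that arms/timepoints of one collection share the same species profile.
    sgb_rng = np.random.default_rng([config.seed, 7919])
    presence_p = sgb_rng.uniform(lo, hi, size=m)
    log_mu = sgb_rng.normal(-6.0, 1.5, size=m) + config.cohort_shift

    logit = np.log(presence_p / (1 - presence_p))[None, :]
    if presence_logit_shift is not None:
        logit = logit + presence_logit_shift
    p = 1.0 / (1.0 + np.exp(-logit))
    present = rng.random((n, m)) < p
    mu = log_mu[None, :]
    if log_mean_shift is not None:
        mu = mu + log_mean_shift
    raw = np.exp(rng.normal(mu, config.log_abundance_sd, size=(n, m)))
    raw *= present
    totals = raw.sum(axis=1, keepdims=True)
    target = rng.uniform(0.85, 1.0, size=(n, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        closed = np.where(totals > 0, raw / totals * target, 0.0)
    return closed


def _standardized_ranks(x: np.ndarray) -> np.ndarray:
    """Column-wise average-tie ranks standardized to mean 0, sd 1."""
    r = stats.rankdata(x, axis=0, method="average").astype(float)
    r -= r.mean(axis=0)
    sd = r.std(axis=0)
    sd[sd == 0] = 1.0
    return r / sd


def _markers(
    rng: np.random.Generator,
    abund: np.ndarray,
    sgb_ids: list[str],
    covs: pd.DataFrame,
    truth: PlantedTruth,
    config: CohortSimConfig,
) -> pd.DataFrame:
    """Markers = direction * planted signal + covariate effects + noise.

    The latent health signal is the effect-weighted sum of standardized
    rank-transformed planted abundances (favourable positive); each
    marker observes it through its own direction, so higher-is-healthy
    markers rise with favourable species.
    """
    n = abund.shape[0]
    z = _standardized_ranks(abund)
    dirs = np.array([truth.direction[s] for s in sgb_ids], dtype=float)
    signal = (z * (dirs * truth.effect_size)[None, :]).sum(axis=1)
    sex = covs["sex"].to_numpy(dtype=float)
    age_z = (covs["age"].to_numpy(dtype=float) - 50) / 13
    bmi_z = (covs["bmi"].to_numpy(dtype=float) - 26) / 4.2
    ce = config.covariate_effects
    covar_part = (
        ce.get("sex", 0.0) * sex + ce.get("age", 0.0) * age_z + ce.get("bmi", 0.0) * bmi_z
    )
    panel = config.marker_panel
    out = {}
    for marker in panel.markers:
        d = panel.direction(marker)
        noise = rng.normal(0, config.marker_noise_sd, size=n)
        out[marker] = d * signal + covar_part + noise
    return pd.DataFrame(out)


def generate_cohort(
    config: CohortSimConfig,
    truth: PlantedTruth | None = None,
    cohort_id: str = "C1",
) -> tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]:
    """One cohort: (AbundanceTable, metadata SampleFrame, MarkerMatrix)."""
    truth = truth or make_planted_truth(config)
    if set(truth.sgb_ids) != set(make_planted_truth(config).sgb_ids):
        raise ValidationError("truth SGB universe inconsistent with config")
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    covs = _covariates(rng, n)
    if config.confound_bmi:
        # BMI loads on the planted species themselves (favourable depleted,
        # unfavourable enriched at high BMI), confounding marker links.
        bmi_z = ((covs["bmi"] - 26) / 4.2).to_numpy()
        dirs = np.array([truth.direction[s] for s in truth.sgb_ids], dtype=float)
        shift = -0.6 * bmi_z[:, None] * dirs[None, :]
        abund = _abundances(rng, n, truth, config,
                            presence_logit_shift=shift, log_mean_shift=shift)
    else:
        abund = _abundances(rng, n, truth, config)
    sample_ids = [f"{cohort_id}_S{i + 1:04d}" for i in range(n)]
    table = AbundanceTable(
        pd.DataFrame(
            abund,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=pd.Index(truth.sgb_ids, name="sgb_id"),
        )
    )
    markers = _markers(rng, abund, truth.sgb_ids, covs, truth, config)
    markers.index = pd.Index(sample_ids, name="sample_id")
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort_id": cohort_id,
            "subject_id": sample_ids,
            "sex": covs["sex"].to_numpy(),
            "age": covs["age"].to_numpy(),
            "bmi": covs["bmi"].to_numpy(),
            "country": "SIM",
            "sequencing_depth": rng.uniform(2e9, 8e9, size=n),
        }
    ).set_index("sample_id", drop=False)
    return table, meta, markers


def generate_multi_cohort(
    configs: list[CohortSimConfig],
    truth: PlantedTruth | None = None,
) -> tuple[dict[str, tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]], PlantedTruth]:
    """Multiple cohorts over one shared SGB universe and planted truth."""
    if not configs:
        raise ValidationError("need at least one cohort config")
    truth = truth or make_planted_truth(configs[0])
    universes = {c.n_sgbs for c in configs}
    if universes != {len(truth.sgb_ids)}:
        raise ValidationError("inconsistent SGB universes across cohorts")
    out = {}
    for i, cfg in enumerate(configs):
        cohort_id = f"C{i + 1}"
        out[cohort_id] = generate_cohort(cfg, truth, cohort_id)
    return out, truth


def standard_multi_cohort_configs(
    seed: int, n_cohorts: int = 3, **overrides
) -> list[CohortSimConfig]:
    """The standard 3-cohort study conditions, with per-cohort mean shifts."""
    shifts = np.linspace(-0.3, 0.3, n_cohorts)
    return [
        replace(
            CohortSimConfig(seed=int(np.random.default_rng([seed, i]).integers(2**31)),
                            cohort_shift=float(shifts[i])),
            **overrides,
        )
        for i in range(n_cohorts)
    ]


def generate_case_control_collection(
    n_datasets: int,
    n_per_arm: int,
    truth: PlantedTruth,
    case_shift: float,
    seed: int,
    base_config: CohortSimConfig | None = None,
    shared_controls: bool = False,
    presence_shift: bool = True,
) -> tuple[list[tuple[AbundanceTable, pd.DataFrame]], dict]:
    """Case-control datasets with cases depleted in favourable species.

    ``case_shift`` > 0 applies a log-fold depletion of favourable and
    enrichment of unfavourable SGBs in cases (log-normal mean shift, and
    the matching presence-logit shift when ``presence_shift`` is on;
    turning it off leaves presence untouched so the perturbation is
    purely abundance-proportional).

    With ``shared_controls`` the first two datasets reuse one control
    arm; the returned overlap map lists the duplicated control ids per
    dataset pair, for shared-control covariance pooling.
    """
    if n_per_arm < 4:
        raise ValidationError("need at least 4 samples per arm")
    base = base_config or CohortSimConfig(n_sgbs=len(truth.sgb_ids))
    if base.n_sgbs != len(truth.sgb_ids):
        raise ValidationError("config SGB universe inconsistent with truth")
    dirs = np.array([truth.direction[s] for s in truth.sgb_ids], dtype=float)
    datasets = []
    overlap: dict[tuple[str, str], list[str]] = {}
    for d in range(n_datasets):
        ds_seed = int(np.random.default_rng([seed, 100 + d]).integers(2**31))
        cfg = replace(base, n_samples=2 * n_per_arm, seed=ds_seed)
        rng = np.random.default_rng([ds_seed, 2])
        status = np.array(["control"] * n_per_arm + ["case"] * n_per_arm)
        case = (status == "case").astype(float)[:, None]
        shift = -case_shift * case * dirs[None, :]
        abund = _abundances(
            rng, cfg.n_samples, truth, cfg,
            presence_logit_shift=shift if presence_shift else None,
            log_mean_shift=shift,
        )
        covs = _covariates(rng, cfg.n_samples)
        ds_id = f"D{d + 1}"
        sample_ids = [f"{ds_id}_S{i + 1:04d}" for i in range(cfg.n_samples)]
        table = AbundanceTable(
            pd.DataFrame(
                abund,
                index=pd.Index(sample_ids, name="sample_id"),
                columns=pd.Index(truth.sgb_ids, name="sgb_id"),
            )
        )
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort_id": ds_id,
                "subject_id": sample_ids,
                "sex": covs["sex"].to_numpy(),
                "age": covs["age"].to_numpy(),
                "bmi": covs["bmi"].to_numpy(),
                "country": "SIM",
                "status": status,
            }
        ).set_index("sample_id", drop=False)
        datasets.append((table, meta))

    if shared_controls and n_datasets >= 2:
        # Dataset 2 reuses dataset 1's control arm verbatim.
        t1, m1 = datasets[0]
        t2, m2 = datasets[1]
        ctrl1 = m1.index[m1["status"] == "control"]
        ctrl2 = m2.index[m2["status"] == "control"]
        data2 = t2.data.copy()
        data2.loc[ctrl2] = t1.data.loc[ctrl1].to_numpy()
        meta2 = m2.copy()
        meta2.loc[ctrl2, ["sex", "age", "bmi"]] = m1.loc[
            ctrl1, ["sex", "age", "bmi"]
        ].to_numpy()
        datasets[1] = (AbundanceTable(data2), meta2)
        overlap[("D1", "D2")] = list(ctrl1)
    return datasets, overlap


def generate_paired_intervention(
    n_subjects: int,
    truth: PlantedTruth,
    response_set: list[str],
    shift: float,
    seed: int,
    base_config: CohortSimConfig | None = None,
    within_sd: float = 0.4,
    decrease_set: list[str] | None = None,
) -> tuple[AbundanceTable, AbundanceTable, pd.DataFrame]:
    """Paired baseline/endpoint tables for a pre/post intervention design.

    Species in ``response_set`` gain ``shift`` at the endpoint; species in
    the optional ``decrease_set`` lose it.

    Each subject carries a latent per-SGB log abundance (between-subject
    spread ``config.log_abundance_sd``) and a presence pattern shared by
    both timepoints; the two timepoints are independent log-normal
    re-draws around that latent value with within-subject spread
    ``within_sd``, and the endpoint adds ``shift`` (natural-log fold) to
    the response-set SGBs.  The shared latent value reproduces the strong
    within-subject temporal correlation of real gut profiles that paired
    tests exploit.
    """
    decrease_set = decrease_set or []
    unknown = (set(response_set) | set(decrease_set)) - set(truth.sgb_ids)
    if unknown:
        raise ValidationError(f"response_set outside SGB universe: {sorted(unknown)}")
    base = base_config or CohortSimConfig(n_sgbs=len(truth.sgb_ids))
    if base.n_sgbs != len(truth.sgb_ids):
        raise ValidationError("config SGB universe inconsistent with truth")
    cfg = replace(base, n_samples=n_subjects,
                  seed=int(np.random.default_rng([seed, 3]).integers(2**31)))
    rng = np.random.default_rng([cfg.seed, 10])
    m = len(truth.sgb_ids)
    lo, hi = cfg.zero_inflation
    sgb_rng = np.random.default_rng([cfg.seed, 7919])
    presence_p = sgb_rng.uniform(lo, hi, size=m)
    log_mu = sgb_rng.normal(-6.0, 1.5, size=m) + cfg.cohort_shift
    present = rng.random((n_subjects, m)) < presence_p[None, :]
    latent = rng.normal(log_mu[None, :], cfg.log_abundance_sd, size=(n_subjects, m))
    mask = np.array([s in set(response_set) for s in truth.sgb_ids], dtype=float)
    mask -= np.array([s in set(decrease_set) for s in truth.sgb_ids], dtype=float)

    def _close(raw: np.ndarray) -> np.ndarray:
        raw = raw * present
        totals = raw.sum(axis=1, keepdims=True)
        target = rng.uniform(0.85, 1.0, size=(n_subjects, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, raw / totals * target, 0.0)

    baseline = _close(np.exp(rng.normal(latent, within_sd)))
    endpoint = _close(np.exp(rng.normal(latent + shift * mask[None, :], within_sd)))
    subjects = [f"SUBJ{i + 1:04d}" for i in range(n_subjects)]
    idx_b = pd.Index([f"{s}_T0" for s in subjects], name="sample_id")
    idx_e = pd.Index([f"{s}_T1" for s in subjects], name="sample_id")
    cols = pd.Index(truth.sgb_ids, name="sgb_id")
    covs = _covariates(rng, n_subjects)
    meta = pd.DataFrame(
        {
            "sample_id": list(idx_b) + list(idx_e),
            "cohort_id": "TRIAL",
            "subject_id": subjects + subjects,
            "sex": np.tile(covs["sex"].to_numpy(), 2),
            "age": np.tile(covs["age"].to_numpy(), 2),
            "bmi": np.tile(covs["bmi"].to_numpy(), 2),
            "timepoint": ["baseline"] * n_subjects + ["endpoint"] * n_subjects,
        }
    ).set_index("sample_id", drop=False)
    return (
        AbundanceTable(pd.DataFrame(baseline, index=idx_b, columns=cols)),
        AbundanceTable(pd.DataFrame(endpoint, index=idx_e, columns=cols)),
        meta,
    )
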