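"""Synthetic intensive-longitudinal cohorts with known linkage density.

The generator produces item-level weekly depression ratings, end-of-treatment
outcomes and follow-up severity series whose ground truth is known, so every
pipeline stage can be tested without clinical data. The latent process is the
estimator's own model class: each patient i carries a stable lag-1 coefficient
matrix A_i (diagonal = autoregression ``a``; off-diagonals drawn around a
patient density delta_i) driving

    x_t = m_t + A_i (x_{t-1} - m_{t-1}) + eps_t,      eps_t ~ N(0, sigma^2 I)

on the logit scale, with a declining patient-specific mean path m_t emulating
acute-phase treatment improvement. Latent states are squashed to [0, 1]
symptom levels, emitted as integer item scores for three instrument-like
scales, and thinned by whole-week missingness. Patient density is
parameterized as the expected TOTAL incoming cross-lag mass per symptom
(off-diagonal mean delta_i / (S - 1)), which keeps densities up to ~1 - a
inside the stability region.

Outcomes: treatment response follows a logistic model on delta_i and final
severity (exit HRSD and the major-depressive-episode flag are generated
consistently with the response classification); end-of-treatment social
adjustment and therapy-skill endpoints are linear in their baseline, the
grand mean and delta_i; follow-up psychiatric status ratings (PSR, 1-6) are
linear in delta_i, grand mean and period with a patient random intercept,
monotone attrition, and clipping to the rating bounds.

Determinism: each patient has an independent RNG substream keyed by patient
index, so regeneration from (config, seed) is bit-identical and inserting a
patient does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigInfeasibleError
from .outcomes import classify_response
from .scales import N_WEEKS, SYMPTOMS, ScaleMap, default_scale_map

_MAX_REJECT = 1000


@dataclass(frozen=True)
class OutcomeParams:
    """Generative coefficients for response, endpoints and follow-up PSR."""

    # logistic response model on (density, final-week mean symptom level)
    response_intercept: float = 8.95
    response_per_density: float = 22.0
    response_per_severity: float = -32.0
    mde_prob_nonresponse: float = 0.55
    # social adjustment (higher = poorer)
    sas_start_base: float = 1.62
    sas_start_per_mean: float = 3.5
    sas_start_noise: float = 0.30
    sas_end_base: float = 0.70
    sas_end_per_start: float = 0.40
    sas_end_per_mean: float = 2.0
    sas_end_per_density: float = -0.65
    sas_end_noise: float = 0.30
    # therapy-skill ratings (patient- and therapist-rated), primary sample only
    skills: bool = True
    skills_mid_base: float = 3.6
    skills_mid_per_mean: float = -1.0
    skills_mid_noise: float = 0.60
    skills_end_base: float = 1.20
    skills_end_per_mid: float = 0.65
    skills_end_per_mean: float = -1.4
    skills_end_per_density: float = 0.8
    skills_end_noise: float = 0.45
    # follow-up psychiatric status ratings
    psr_base: float = 1.55
    psr_per_density: float = -1.2
    psr_per_mean: float = 2.0
    psr_per_period: float = -0.02
    psr_intercept_sd: float = 0.55
    psr_noise: float = 0.60
    attrition_per_period: float = 0.045
    endpoint_missing_rate: float = 0.15


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification of a synthetic cohort."""

    n_patients: int = 475
    n_weeks: int = N_WEEKS
    n_symptoms: int = 9
    # cross-lag density: expected total incoming cross-lag mass per symptom
    density_mean: float = 0.10
    density_sd: float = 0.45
    coupling_sd: float = 0.03
    autoreg: float = 0.25
    innovation_sd: float = 0.85
    # share of innovation variance from a common (general-severity) factor
    innovation_cor: float = 0.7
    # declining mean path on the logit scale
    trend_start: float = -0.75
    trend_start_sd: float = 0.50
    trend_change: float = -1.2
    trend_change_sd: float = 0.45
    symptom_trend_sd: float = 0.55
    # item emission and missingness
    item_noise_sd: float = 0.15
    missing_week_rate: float = 0.09
    # outcome structure
    outcome: OutcomeParams = field(default_factory=OutcomeParams)
    response_threshold: int = 12
    arms: tuple[str, ...] = ("c-ct", "fluoxetine", "placebo", "assessment_only")
    n_periods: int = 8
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arms"] = list(self.arms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "outcome" in d and isinstance(d["outcome"], dict):
            d["outcome"] = OutcomeParams(**d["outcome"])
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def primary_like(n_patients: int = 475, seed: int = 0, **overrides) -> CohortConfig:
    """Default study conditions: larger-trial-like cohort (threshold 12, 8 periods)."""
    return dataclasses.replace(CohortConfig(), n_patients=n_patients, seed=seed, **overrides)


def replication_like(n_patients: int = 146, seed: int = 0, **overrides) -> CohortConfig:
    """Smaller-trial-like cohort: response threshold 9, 6 follow-up periods, 2 arms."""
    base = CohortConfig(
        n_patients=n_patients,
        density_mean=0.25,
        trend_start=-0.95,
        response_threshold=9,
        arms=("c-ct", "assessment_only"),
        n_periods=6,
        seed=seed,
        outcome=dataclasses.replace(OutcomeParams(), skills=False, psr_base=1.15,
                                    response_intercept=5.2),
    )
    return dataclasses.replace(base, **overrides)


def null_cohort(n_patients: int = 500, seed: int = 0, **overrides) -> CohortConfig:
    """Null condition: zero cross-lag matrix, flat mean path, independent
    innovations, response a pure base rate.

    The shared declining trend and the common innovation factor are disabled
    because both induce positive cross-lag estimates without any coupling (a
    shared forecastable trend directly, and contemporaneous co-fluctuation via
    measurement-error spillover at the item level); the null condition is a
    zero generative cross-lag matrix with no shared signal of any kind, so
    estimated SLD is centered at zero.
    """
    base = CohortConfig(
        n_patients=n_patients,
        density_mean=0.0,
        density_sd=0.0,
        coupling_sd=0.0,
        innovation_cor=0.0,
        trend_change=0.0,
        trend_change_sd=0.0,
        symptom_trend_sd=0.0,
        trend_start=-1.0,
        seed=seed,
        outcome=dataclasses.replace(
            OutcomeParams(),
            response_intercept=0.7547,  # logit(0.68)
            response_per_density=0.0,
            response_per_severity=0.0,
        ),
    )
    return dataclasses.replace(base, **overrides)


PRESETS = {
    "primary-like": primary_like,
    "replication-like": replication_like,
    "null": null_cohort,
}


# ---------------------------------------------------------------------------
# per-patient generative steps


def _patient_rngs(seed: int, index: int, n_streams: int = 5):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return [np.random.default_rng(c) for c in ss.spawn(n_streams)]


def draw_patient_dynamics(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Draw (lag matrix A_i, density delta_i); reject until spectrally stable."""
    S = config.n_symptoms
    bound = 1.0 - config.autoreg
    for _ in range(_MAX_REJECT):
        delta = rng.normal(config.density_mean, config.density_sd)
        if -bound < delta < bound:
            break
    else:
        raise ConfigInfeasibleError(
            f"could not draw a density inside (-{bound:.2f}, {bound:.2f})"
        )
    per_entry = delta / (S - 1)
    for _ in range(_MAX_REJECT):
        A = rng.normal(per_entry, config.coupling_sd, size=(S, S))
        np.fill_diagonal(A, config.autoreg)
        if np.max(np.abs(np.linalg.eigvals(A))) < 1.0:
            return A, float(delta)
    raise ConfigInfeasibleError(
        f"no stable lag matrix after {_MAX_REJECT} draws "
        f"(autoreg={config.autoreg}, density={delta:.3f})"
    )


def simulate_latent_series(
    A: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one patient's 13 x 9 matrix of [0, 1] symptom levels.

    Draws the patient's mean path (level intercept, improvement magnitude,
    per-symptom slope jitter), runs the lag-1 recursion on the logit scale
    and squashes to levels.
    """
    T, S = config.n_weeks, config.n_symptoms
    alpha = rng.normal(config.trend_start, config.trend_start_sd)
    change = rng.normal(config.trend_change, config.trend_change_sd)
    jitter = rng.normal(0.0, config.symptom_trend_sd, size=S)
    tgrid = np.arange(T) / max(T - 1, 1)
    m = alpha + np.outer(tgrid, change + jitter)  # T x S mean path
    c = config.innovation_cor
    idio = rng.normal(0.0, 1.0, size=(T, S))
    common = rng.normal(0.0, 1.0, size=(T, 1))
    eps = config.innovation_sd * (np.sqrt(c) * common + np.sqrt(1.0 - c) * idio)
    x = np.empty((T, S))
    x[0] = m[0] + eps[0]
    for t in range(1, T):
        x[t] = m[t] + A @ (x[t - 1] - m[t - 1]) + eps[t]
    return expit(x)


def apply_missingness(
    levels: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Remove whole weeks at random (week 1 always retained).

    Returns (masked levels with NaN rows, boolean observed-week vector).
    """
    T = levels.shape[0]
    observed = rng.random(T) >= config.missing_week_rate
    observed[0] = True
    out = levels.copy()
    out[~observed] = np.nan
    return out, observed


def _map_arrays(scale_map: ScaleMap):
    """(instruments, item_ids, max_scores, symptom indices) for all mapped items."""
    frame = scale_map.to_frame()
    if frame["max_score"].isna().any():
        raise ConfigInfeasibleError("generator requires max_score for every mapped item")
    sym_index = {s: i for i, s in enumerate(SYMPTOMS)}
    return (
        frame["instrument"].to_numpy(),
        frame["item_id"].to_numpy(),
        frame["max_score"].to_numpy(dtype=int),
        np.array([sym_index[s] for s in frame["symptom"]]),
    )


def emit_items(
    levels: np.ndarray,
    observed: np.ndarray,
    patient_id: str,
    map_arrays,
    item_noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit integer item scores: round(level * max + noise), clipped to [0, max]."""
    instruments, item_ids, max_scores, sym_idx = map_arrays
    weeks = np.flatnonzero(observed) + 1
    n_items = len(item_ids)
    lv = levels[weeks - 1][:, sym_idx]  # n_obs_weeks x n_items
    noise = rng.normal(0.0, item_noise_sd, size=lv.shape) * max_scores
    scores = np.clip(np.rint(lv * max_scores + noise), 0, max_scores).astype(int)
    n_obs = len(weeks)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "week": np.repeat(weeks, n_items),
            "instrument": np.tile(instruments, n_obs),
            "item_id": np.tile(item_ids, n_obs),
            "score": scores.ravel(),
            "max_score": np.tile(max_scores, n_obs),
        }
    )


def generate_outcomes(
    patient_id: str,
    delta: float,
    levels: np.ndarray,
    observed: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[dict, list[dict]]:
    """Generate one patient's outcome record and follow-up PSR rows."""
    par = config.outcome
    grand_mean_true = float(levels.mean())
    final_level = float(levels[-1].mean())
    eligible = int(observed.sum()) >= 3

    p_resp = expit(
        par.response_intercept
        + par.response_per_density * delta
        + par.response_per_severity * final_level
    )
    responder = bool(rng.random() < p_resp)
    thr = config.response_threshold
    base_sev = 52.0 * final_level
    if responder:
        mde = False
        exit_hrsd = int(np.clip(np.rint(base_sev * 0.6 + rng.normal(0, 2.0)), 0, thr))
    else:
        mde = bool(rng.random() < par.mde_prob_nonresponse)
        lo = 0 if mde else thr + 1
        exit_hrsd = int(np.clip(np.rint(base_sev + 4.0 + abs(rng.normal(0, 4.0))), lo, 52))
    assert classify_response(exit_hrsd, mde, thr) == responder

    sas_start = par.sas_start_base + par.sas_start_per_mean * grand_mean_true + rng.normal(
        0, par.sas_start_noise
    )
    sas_end = (
        par.sas_end_base
        + par.sas_end_per_start * sas_start
        + par.sas_end_per_mean * grand_mean_true
        + par.sas_end_per_density * delta
        + rng.normal(0, par.sas_end_noise)
    )
    if rng.random() < par.endpoint_missing_rate:
        sas_end = np.nan

    row = {
        "patient_id": patient_id,
        "eligible": eligible,
        "exit_hrsd": exit_hrsd,
        "mde_at_exit": mde,
        "responder": responder,
        "arm": rng.choice(config.arms) if responder else "",
        "sas_start": sas_start,
        "sas_end": sas_end,
    }
    if par.skills:
        for rater in ("pat", "ther"):
            mid = par.skills_mid_base + par.skills_mid_per_mean * grand_mean_true + rng.normal(
                0, par.skills_mid_noise
            )
            end = (
                par.skills_end_base
                + par.skills_end_per_mid * mid
                + par.skills_end_per_mean * grand_mean_true
                + par.skills_end_per_density * delta
                + rng.normal(0, par.skills_end_noise)
            )
            if rng.random() < par.endpoint_missing_rate:
                end = np.nan
            row[f"skills_{rater}_mid"] = mid
            row[f"skills_{rater}_end"] = end

    psr_rows: list[dict] = []
    if responder:
        b_i = rng.normal(0, par.psr_intercept_sd)
        for period in range(1, config.n_periods + 1):
            if period > 1 and rng.random() < par.attrition_per_period:
                break
            psr = (
                par.psr_base
                + par.psr_per_density * delta
                + par.psr_per_mean * grand_mean_true
                + par.psr_per_period * (period - 1)
                + b_i
                + rng.normal(0, par.psr_noise)
            )
            psr_rows.append(
                {
                    "patient_id": patient_id,
                    "period": period,
                    "psr": float(np.clip(psr, 1.0, 6.0)),
                }
            )
    return row, psr_rows


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SyntheticCohort:
    """A generated cohort: observable tables plus a fire-walled ground truth.

    The analysis path consumes only ``items`` (or ``series_long`` for the
    series-level fast path), ``outcomes`` and ``psr``; ``ground_truth`` and
    ``lag_matrices`` exist for test oracles and are written into a separate
    ``ground_truth/`` directory.
    """

    config: CohortConfig
    items: pd.DataFrame | None
    series_long: pd.DataFrame
    outcomes: pd.DataFrame
    psr: pd.DataFrame
    ground_truth: pd.DataFrame
    lag_matrices: dict[str, np.ndarray]

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        if self.items is not None:
            paths["items"] = str(outdir / "items.csv")
            self.items.to_csv(paths["items"], index=False)
        paths["series"] = str(outdir / "symptom_series.csv")
        self.series_long.to_csv(paths["series"], index=False)
        paths["outcomes"] = str(outdir / "outcomes.csv")
        self.outcomes.to_csv(paths["outcomes"], index=False)
        paths["psr"] = str(outdir / "psr.csv")
        self.psr.to_csv(paths["psr"], index=False)
        gt_dir = outdir / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        paths["ground_truth"] = str(gt_dir / "ground_truth.json")
        gt = {
            "patients": self.ground_truth.to_dict(orient="records"),
            "lag_matrices": {k: v.tolist() for k, v in self.lag_matrices.items()},
        }
        with open(paths["ground_truth"], "w") as fh:
            json.dump(gt, fh)
        paths["config"] = str(outdir / "config.yaml")
        self.config.to_yaml(paths["config"])
        return paths


def generate_cohort(
    config: CohortConfig,
    scale_map: ScaleMap | None = None,
    item_level: bool = True,
) -> SyntheticCohort:
    """Generate a full cohort under ``config``.

    With ``item_level=False`` the instrument-emission stage is skipped and
    ``series_long`` carries the noiseless symptom levels directly (fast path
    for Monte-Carlo studies of the estimator and outcome models).
    """
    if not (0 <= config.missing_week_rate < 1):
        raise ConfigInfeasibleError("missing_week_rate must be in [0, 1)")
    scale_map = scale_map or default_scale_map()
    map_arrays = _map_arrays(scale_map) if item_level else None

    item_frames, series_frames, out_rows, psr_rows, gt_rows = [], [], [], [], []
    lag_matrices: dict[str, np.ndarray] = {}
    width = max(4, len(str(config.n_patients)))
    weeks_grid = np.arange(1, config.n_weeks + 1)

    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        rng_dyn, rng_series, rng_emit, rng_miss, rng_out = _patient_rngs(config.seed, i)
        A, delta = draw_patient_dynamics(config, rng_dyn)
        levels = simulate_latent_series(A, config, rng_series)
        masked, observed = apply_missingness(levels, config, rng_miss)

        if item_level:
            item_frames.append(
                emit_items(levels, observed, pid, map_arrays, config.item_noise_sd, rng_emit)
            )
        series_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "week": np.repeat(weeks_grid, config.n_symptoms),
                    "symptom": np.tile(np.array(SYMPTOMS[: config.n_symptoms], dtype=object),
                                       config.n_weeks),
                    "value": masked.ravel(),
                }
            )
        )
        row, prow = generate_outcomes(pid, delta, levels, observed, config, rng_out)
        out_rows.append(row)
        psr_rows.extend(prow)
        gt_rows.append(
            {
                "patient_id": pid,
                "delta": delta,
                "grand_mean_true": float(levels.mean()),
                "final_level": float(levels[-1].mean()),
                "observed_weeks": int(observed.sum()),
                "spectral_radius": float(np.max(np.abs(np.linalg.eigvals(A)))),
            }
        )
        lag_matrices[pid] = A

    items = pd.concat(item_frames, ignore_index=True) if item_level else None
    psr = pd.DataFrame(psr_rows, columns=["patient_id", "period", "psr"])
    return SyntheticCohort(
        config=config,
        items=items,
        series_long=pd.concat(series_frames, ignore_index=True),
        outcomes=pd.DataFrame(out_rows),
        psr=psr,
        ground_truth=pd.DataFrame(gt_rows),
        lag_matrices=lag_matrices,
    )
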