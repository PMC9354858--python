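"""Pipeline orchestration and publication-style reporting.

``run_pipeline`` executes scales -> linkage -> outcome models on CSV inputs
and writes four report tables (descriptives, logistic response model, linear
endpoint models, mixed follow-up model) plus the per-patient linkage table,
mean edge-matrix exports for responders and non-responders, and a JSON run
report with a config hash and the patient counts at each filter stage. Every
table gets a YAML sidecar carrying the config hash so each numeric cell can
be traced to a configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError, SldnetError
from .outcomes import (
    EndpointModel,
    FollowupModel,
    ResponseModel,
    classify_response,
    distribution_overlap,
    effect_size_d,
)
from .scales import ScaleMap, default_scale_map, read_items_csv, score_cohort
from .sld import SymptomLinkageModel

logger = logging.getLogger("sldnet")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (echoed into every output header)."""

    items_csv: str
    outcomes_csv: str
    psr_csv: str | None = None
    scale_map_yaml: str | None = None
    out_dir: str = "sldnet_out"
    # sample convention
    response_threshold: int = 12
    n_periods: int = 8
    # estimator options
    min_items: int = 1
    min_lag_rows: int = 4
    min_coefficients: int = 48
    min_weeks: int = 3
    shrinkage: bool = False
    detrend: bool = False
    # model options
    covariance: str = "random_intercept"
    trim_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.response_threshold not in (12, 9):
            raise SldnetError("response_threshold must be 12 or 9")
        if not (0 < self.trim_alpha < 1):
            raise SldnetError("trim_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, created: list[str]) -> None:
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"config_hash": cfg_hash, "version": __version__}, fh)
    created.extend([str(path), str(sidecar)])


def summarize_descriptives(
    linkage: pd.DataFrame,
    outcomes: pd.DataFrame,
    psr: pd.DataFrame | None,
    n_periods: int = 8,
) -> pd.DataFrame:
    """Table-1-style descriptives: n, mean or %, SD per analyzed variable."""
    if linkage.empty or outcomes.empty:
        raise SldnetError("empty cohort")
    drop = [c for c in linkage.columns if c != "patient_id" and c in outcomes.columns]
    outcomes = outcomes.drop(columns=drop)
    merged = outcomes.merge(linkage, on="patient_id", how="inner")
    merged = merged[merged["eligible"].astype(bool)]
    rows = []

    def stat(label, series):
        s = pd.to_numeric(series, errors="coerce").dropna()
        rows.append(
            {
                "variable": label,
                "n": int(len(s)),
                "mean_or_pct": float(s.mean()) if len(s) else np.nan,
                "sd": float(s.std(ddof=1)) if len(s) > 1 else np.nan,
            }
        )

    stat("Symptom mean", merged["grand_mean"])
    stat("Symptom standard deviation", merged["grand_sd"])
    stat("Symptom linkage density", merged["sld"])
    for col, label in [
        ("skills_pat_mid", "Patient-rated skills mid-treatment"),
        ("skills_pat_end", "Patient-rated skills end of treatment"),
        ("skills_ther_mid", "Therapist-rated skills mid-treatment"),
        ("skills_ther_end", "Therapist-rated skills end of treatment"),
    ]:
        if col in merged.columns:
            stat(label, merged[col])
    stat("Social adjustment at the start", merged["sas_start"])
    stat("Social adjustment at the end", merged["sas_end"])
    resp = merged["responder"].astype(bool)
    rows.append(
        {
            "variable": "Responded (%)",
            "n": int(len(resp)),
            "mean_or_pct": float(100.0 * resp.mean()),
            "sd": np.nan,
        }
    )
    if psr is not None and not psr.empty:
        eligible_ids = set(merged["patient_id"])
        psr = psr[psr["patient_id"].isin(eligible_ids)]
        for period in range(1, n_periods + 1):
            sub = psr[psr["period"] == period]["psr"]
            rows.append(
                {
                    "variable": f"MDD PSR period {period}",
                    "n": int(len(sub)),
                    "mean_or_pct": float(sub.mean()) if len(sub) else np.nan,
                    "sd": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute scales -> linkage -> models; returns the JSON-able run report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    report: dict = {"config": cfg.to_dict(), "config_hash": cfg_hash,
                    "version": __version__, "stages": {}}
    created: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # remove partial outputs of the failed stage
                for p in created:
                    Path(p).unlink(missing_ok=True)
                raise PipelineStageError(name, str(exc)) from exc
        return deco

    @stage("score-scales")
    def tidy():
        scale_map = (
            ScaleMap.from_yaml(cfg.scale_map_yaml) if cfg.scale_map_yaml else default_scale_map()
        )
        items = read_items_csv(cfg.items_csv)
        tidy = score_cohort(items, scale_map, min_items=cfg.min_items)
        _write_table(tidy, out / "symptom_series.csv", cfg_hash, created)
        report["stages"]["score_scales"] = {
            "n_items": int(len(items)),
            "n_patients": int(items["patient_id"].nunique()),
        }
        return tidy

    @stage("estimate-sld")
    def linkage():
        model = SymptomLinkageModel(
            tidy,
            min_lag_rows=cfg.min_lag_rows,
            min_coefficients=cfg.min_coefficients,
            min_weeks=cfg.min_weeks,
            detrend=cfg.detrend,
            shrinkage=cfg.shrinkage,
        )
        res = model.fit()
        _write_table(res.patient_table, out / "patient_linkage.csv", cfg_hash, created)
        _write_table(res.coefficients, out / "pair_coefficients.csv", cfg_hash, created)
        report["stages"]["estimate_sld"] = {
            "n_patients": res.n_patients,
            "n_eligible": res.n_eligible,
        }
        return res

    @stage("fit-models")
    def models():
        outcomes = pd.read_csv(cfg.outcomes_csv, dtype={"patient_id": str})
        # response status is recomputed from its definition; generator-side
        # flags are dropped so the analysis path never consumes them
        outcomes = outcomes.drop(columns=["eligible", "responder"], errors="ignore")
        ptab = linkage.patient_table
        merged = outcomes.merge(ptab, on="patient_id", how="inner")
        merged = merged[merged["eligible"].astype(bool) & merged["sld"].notna()].copy()
        merged["responder"] = classify_response(
            merged["exit_hrsd"].to_numpy(),
            merged["mde_at_exit"].to_numpy(),
            cfg.response_threshold,
        )
        n_resp = int(merged["responder"].sum())
        report["stages"]["fit_models"] = {
            "n_analyzed": int(len(merged)),
            "n_responders": n_resp,
        }

        resp_res = ResponseModel(merged).fit()
        _write_table(resp_res.table(), out / "table2_response.csv", cfg_hash, created)

        endpoint_specs = [("sas_end", "sas_start", "Social adjustment")]
        for rater in ("pat", "ther"):
            if f"skills_{rater}_end" in merged.columns:
                endpoint_specs.append(
                    (f"skills_{rater}_end", f"skills_{rater}_mid", f"Skills ({rater})")
                )
        t3 = []
        for endpoint, baseline, label in endpoint_specs:
            try:
                tab = EndpointModel(merged, endpoint, baseline).fit().table()
            except SldnetError as exc:
                logger.warning("endpoint %s skipped: %s", label, exc)
                continue
            tab.insert(0, "model", label)
            t3.append(tab)
        _write_table(
            pd.concat(t3, ignore_index=True) if t3 else pd.DataFrame(),
            out / "table3_endpoints.csv", cfg_hash, created,
        )

        table4 = pd.DataFrame()
        followup = None
        if cfg.psr_csv:
            psr = pd.read_csv(cfg.psr_csv, dtype={"patient_id": str})
            sub = merged[merged["responder"]][
                ["patient_id", "arm", "grand_mean", "grand_sd", "sld"]
            ]
            long = psr.merge(sub, on="patient_id", how="inner")
            if not long.empty:
                followup = FollowupModel(long, covariance=cfg.covariance).fit(
                    trim=True, alpha=cfg.trim_alpha
                )
                table4 = followup.anova_table()
        _write_table(table4, out / "table4_followup.csv", cfg_hash, created)

        # effect size and distribution overlap of SLD by response status
        sld_r = merged.loc[merged["responder"], "sld"]
        sld_n = merged.loc[~merged["responder"], "sld"]
        extras = {}
        if len(sld_r) >= 2 and len(sld_n) >= 2:
            ov = distribution_overlap(sld_r, sld_n)
            _write_table(ov.to_frame(), out / "sld_distribution.csv", cfg_hash, created)
            extras = {"cohens_d": effect_size_d(sld_r, sld_n), "overlap": ov.overlap}
        report["stages"]["fit_models"].update(extras)

        for group, name in [(merged.loc[merged["responder"], "patient_id"], "responders"),
                            (merged.loc[~merged["responder"], "patient_id"], "nonresponders")]:
            mat = linkage.edge_matrix(group)
            _write_table(mat.reset_index(), out / f"edges_{name}.csv", cfg_hash, created)
        return merged

    @stage("report")
    def table1():
        outcomes = models
        psr = pd.read_csv(cfg.psr_csv, dtype={"patient_id": str}) if cfg.psr_csv else None
        t1 = summarize_descriptives(
            linkage.patient_table, outcomes, psr, n_periods=cfg.n_periods
        )
        _write_table(t1, out / "table1_descriptives.csv", cfg_hash, created)
        return t1

    tables = sorted(p for p in created if p.endswith(".csv"))
    report["tables"] = [Path(p).name for p in tables]
    # content fingerprint: stable across output locations for identical inputs
    digest = hashlib.sha256()
    for p in tables:
        digest.update(Path(p).name.encode())
        digest.update(Path(p).read_bytes())
    report["report_hash"] = digest.hexdigest()[:16]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
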