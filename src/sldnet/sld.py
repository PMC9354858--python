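"""Per-patient symptom linkage density (SLD) estimation.

SLD summarizes how strongly a patient's depressive symptoms are linked from
one week to the next. For each ordered pair of distinct symptoms (j, k) among
the nine composite scales, a lag-1 regression

    k_t = b0 + b1 * k_{t-1} + b2 * j_{t-1}

is fitted by ordinary least squares within the patient, after standardizing
each symptom series to mean 0 / SD 1 over that patient's observed weeks. The
cross-lag coefficient b2 measures how last week's level of symptom j predicts
this week's level of symptom k, over and above k's own persistence. With nine
symptoms there are 9 * 8 = 72 ordered pairs; SLD is the unweighted mean of the
retained b2 coefficients. Alongside SLD, each patient's grand mean and grand
standard deviation pool all non-missing week x symptom scale values; outcome
models control them so SLD carries incremental information.

Lagged rows require consecutive calendar weeks (both t-1 and t observed); a
pair is skipped when fewer than ``min_lag_rows`` usable rows remain or the
design is collinear, and a symptom with fewer than three observations or zero
variance drops every pair it participates in. An SLD built from fewer than
``min_coefficients`` retained pairs is flagged as unreliable (NaN by default).

The cohort-level entry point is :class:`SymptomLinkageModel`, whose ``fit``
returns a :class:`SymptomLinkageResults` carrying the per-patient table, the
long coefficient table, Cronbach's alpha across the 72 coefficient columns,
and mean edge-matrix exports for network-style displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError, ReliabilityUndefinedError
from .scales import SYMPTOMS, SymptomSeries, series_from_long

#: Default minimum usable lagged rows per pair: 3 parameters + 1 df.
MIN_LAG_ROWS = 4
#: Default minimum retained coefficients for a valid SLD.
MIN_COEFFICIENTS = 48
#: Default minimum observed weeks for patient eligibility.
MIN_WEEKS = 3

_COND_MAX = 1e10  # condition-number cutoff for a usable lagged design


def standardize_series(x: np.ndarray) -> np.ndarray:
    """Within-patient z-scores over observed weeks (sample SD), NaN preserved.

    Raises :class:`DegenerateSeriesError` with fewer than 3 non-missing values
    or zero variance; pairs involving such a symptom are skipped upstream.
    """
    x = np.asarray(x, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 3:
        raise DegenerateSeriesError(f"need >= 3 observed values, got {int(obs.sum())}")
    sd = np.std(x[obs], ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("zero variance series")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - np.mean(x[obs])) / sd
    return out


def detrend_series(x: np.ndarray, weeks: np.ndarray | None = None) -> np.ndarray:
    """Remove a least-squares linear trend over observed weeks (NaN preserved)."""
    x = np.asarray(x, dtype=float)
    if weeks is None:
        weeks = np.arange(1, len(x) + 1, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 3:
        return x.copy()
    b, a = np.polyfit(weeks[obs], x[obs], 1)
    out = np.full_like(x, np.nan)
    out[obs] = x[obs] - (a + b * weeks[obs])
    return out


@dataclass(frozen=True)
class LaggedPairResult:
    """OLS solution of one lag-1 cross-regression (standardized series)."""

    source: str  # symptom j, lagged predictor
    target: str  # symptom k, outcome
    beta2: float
    beta1: float
    beta0: float
    se_beta2: float
    n_lag_rows: int


def fit_lagged_pair(
    k_std: np.ndarray,
    j_std: np.ndarray,
    min_rows: int = MIN_LAG_ROWS,
    source: str = "j",
    target: str = "k",
) -> LaggedPairResult | None:
    """Fit ``k_t ~ 1 + k_{t-1} + j_{t-1}`` over usable consecutive-week rows.

    Series are aligned on calendar position: row t is usable when k_t, k_{t-1}
    and j_{t-1} are all observed. Returns None (pair skipped) with too few
    rows or a collinear design.
    """
    k_std = np.asarray(k_std, dtype=float)
    j_std = np.asarray(j_std, dtype=float)
    y = k_std[1:]
    klag = k_std[:-1]
    jlag = j_std[:-1]
    ok = np.isfinite(y) & np.isfinite(klag) & np.isfinite(jlag)
    n = int(ok.sum())
    if n < min_rows:
        return None
    X = np.column_stack([np.ones(n), klag[ok], jlag[ok]])
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > _COND_MAX:
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y[ok], rcond=None)
    resid = y[ok] - X @ beta
    dof = n - 3
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se2 = float(np.sqrt(sigma2 * xtx_inv[2, 2])) if dof > 0 else np.nan
    return LaggedPairResult(
        source=source,
        target=target,
        beta2=float(beta[2]),
        beta1=float(beta[1]),
        beta0=float(beta[0]),
        se_beta2=se2,
        n_lag_rows=n,
    )


def grand_moments(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD pooled over all non-missing week x symptom values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return (float(v.mean()) if v.size else float("nan"), float("nan"))
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class PatientLinkage:
    """A patient's linkage-density estimate and its data-sufficiency metadata."""

    patient_id: str
    sld: float
    grand_mean: float
    grand_sd: float
    n_weeks_used: int
    n_coefficients: int
    eligible: bool
    sld_reliable: bool
    coefficients: list[LaggedPairResult] = field(default_factory=list)

    def coefficient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": self.patient_id,
                    "j": c.source,
                    "k": c.target,
                    "beta2": c.beta2,
                    "se_beta2": c.se_beta2,
                    "n_lag_rows": c.n_lag_rows,
                }
                for c in self.coefficients
            ],
            columns=["patient_id", "j", "k", "beta2", "se_beta2", "n_lag_rows"],
        )


def _standardized_matrix(
    series: SymptomSeries, detrend: bool
) -> tuple[np.ndarray, list[int]]:
    """Standardize each symptom column; return matrix and usable column indices."""
    Z = np.full_like(series.values, np.nan, dtype=float)
    usable = []
    for s in range(len(series.symptoms)):
        col = series.values[:, s]
        if detrend:
            col = detrend_series(col)
        try:
            Z[:, s] = standardize_series(col)
        except DegenerateSeriesError:
            continue
        usable.append(s)
    return Z, usable


def _wholeweek_pattern(values: np.ndarray, cols: list[int]) -> bool:
    """True when every week is either fully observed or fully missing on ``cols``."""
    sub = np.isfinite(values[:, cols])
    return bool(np.all(sub.all(axis=1) | ~sub.any(axis=1)))


def _fit_pairs_batched(
    Z: np.ndarray, cols: list[int], symptoms: tuple[str, ...], min_rows: int
) -> list[LaggedPairResult] | None:
    """Vectorized all-pairs OLS for whole-week missingness patterns.

    All pairs then share the same usable rows (weeks t with t-1 and t both
    observed), so the 72 normal-equation systems can be assembled from one set
    of cross-products and solved in a single batched call. Verified in tests
    to match the per-pair path exactly.
    """
    obs_week = np.isfinite(Z[:, cols]).all(axis=1)
    rows = obs_week[1:] & obs_week[:-1]
    n = int(rows.sum())
    if n < min_rows:
        return []
    L = Z[:-1][rows][:, cols]  # lagged values, n x m
    C = Z[1:][rows][:, cols]  # current values, n x m
    m = len(cols)
    G = L.T @ L
    H = L.T @ C
    g1 = L.sum(axis=0)
    c1 = C.sum(axis=0)
    yy = np.einsum("ij,ij->j", C, C)

    jj, kk = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    mask = jj != kk
    j_idx, k_idx = jj[mask], kk[mask]
    npair = len(j_idx)

    XtX = np.empty((npair, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = g1[k_idx]
    XtX[:, 0, 2] = XtX[:, 2, 0] = g1[j_idx]
    XtX[:, 1, 1] = G[k_idx, k_idx]
    XtX[:, 1, 2] = XtX[:, 2, 1] = G[k_idx, j_idx]
    XtX[:, 2, 2] = G[j_idx, j_idx]
    Xty = np.empty((npair, 3))
    Xty[:, 0] = c1[k_idx]
    Xty[:, 1] = H[k_idx, k_idx]
    Xty[:, 2] = H[j_idx, k_idx]

    svals = np.linalg.svd(XtX, compute_uv=False)
    good = (svals[:, -1] > 0) & (svals[:, 0] / np.where(svals[:, -1] > 0, svals[:, -1], 1.0) <= _COND_MAX**2)
    out: list[LaggedPairResult] = []
    if not good.any():
        return out
    beta = np.full((npair, 3), np.nan)
    try:
        beta[good] = np.linalg.solve(XtX[good], Xty[good][..., None])[..., 0]
    except np.linalg.LinAlgError:
        # a numerically singular pair slipped through the SVD screen:
        # defer to the per-pair path, which screens on cond(X) directly
        return None
    dof = n - 3
    # residual sum of squares via y'y - b'X'y
    rss = yy[k_idx] - np.einsum("ij,ij->i", beta, Xty)
    rss = np.maximum(rss, 0.0)
    if dof > 0:
        inv = np.full((npair, 3, 3), np.nan)
        inv[good] = np.linalg.inv(XtX[good])
        se2 = np.sqrt(rss / dof * inv[:, 2, 2])
    else:
        se2 = np.full(npair, np.nan)
    labels = [symptoms[c] for c in cols]
    order = np.lexsort((k_idx, j_idx))  # deterministic (j, k) lexicographic order
    for p in order:
        if not good[p]:
            continue
        out.append(
            LaggedPairResult(
                source=labels[j_idx[p]],
                target=labels[k_idx[p]],
                beta2=float(beta[p, 2]),
                beta1=float(beta[p, 1]),
                beta0=float(beta[p, 0]),
                se_beta2=float(se2[p]),
                n_lag_rows=n,
            )
        )
    return out


def compute_sld(
    series: SymptomSeries,
    min_lag_rows: int = MIN_LAG_ROWS,
    min_coefficients: int = MIN_COEFFICIENTS,
    min_weeks: int = MIN_WEEKS,
    detrend: bool = False,
) -> PatientLinkage:
    """Estimate one patient's SLD, grand mean and grand SD.

    Iterates all ordered symptom pairs (j, k), j != k, in lexicographic
    order. Ineligible patients (< ``min_weeks`` observed weeks) return an
    all-NaN record flagged ``eligible=False``; an SLD from fewer than
    ``min_coefficients`` retained pairs is flagged ``sld_reliable=False`` and
    reported as NaN.
    """
    gm, gs = grand_moments(series.values)
    if series.observed_weeks < min_weeks:
        return PatientLinkage(
            patient_id=series.patient_id,
            sld=float("nan"),
            grand_mean=gm,
            grand_sd=gs,
            n_weeks_used=series.observed_weeks,
            n_coefficients=0,
            eligible=False,
            sld_reliable=False,
        )

    Z, cols = _standardized_matrix(series, detrend)
    symptoms = tuple(series.symptoms)
    coeffs: list[LaggedPairResult] = []
    if cols:
        batched = None
        if _wholeweek_pattern(series.values, cols):
            batched = _fit_pairs_batched(Z, cols, symptoms, min_lag_rows)
        if batched is not None:
            coeffs = batched
        else:
            labels = sorted(symptoms[c] for c in cols)
            idx = {symptoms[c]: c for c in cols}
            for j in labels:
                for k in labels:
                    if j == k:
                        continue
                    res = fit_lagged_pair(
                        Z[:, idx[k]], Z[:, idx[j]], min_rows=min_lag_rows, source=j, target=k
                    )
                    if res is not None:
                        coeffs.append(res)

    n_coef = len(coeffs)
    reliable = n_coef >= min_coefficients
    sld = float(np.mean([c.beta2 for c in coeffs])) if (n_coef and reliable) else float("nan")
    return PatientLinkage(
        patient_id=series.patient_id,
        sld=sld,
        grand_mean=gm,
        grand_sd=gs,
        n_weeks_used=series.observed_weeks,
        n_coefficients=n_coef,
        eligible=True,
        sld_reliable=reliable,
        coefficients=coeffs,
    )


def cronbach_alpha(wide: pd.DataFrame) -> float:
    """Cronbach's alpha over item columns using pairwise-complete covariances.

    Here the "items" are the 72 (j, k) cross-lag coefficients and the cases
    are patients.
    """
    cols = [c for c in wide.columns if wide[c].notna().sum() >= 2]
    wide = wide[cols]
    k = wide.shape[1]
    if k < 2 or wide.dropna(how="all").shape[0] < 3:
        raise ReliabilityUndefinedError("need >= 2 coefficient columns over >= 3 patients")
    cov = wide.cov()  # pairwise-complete
    if cov.isna().any().any():
        cov = cov.fillna(0.0)
    total = float(cov.to_numpy().sum())
    if total == 0:
        raise ReliabilityUndefinedError("zero total covariance")
    item_var = float(np.trace(cov.to_numpy()))
    return k / (k - 1) * (1 - item_var / total)


class SymptomLinkageModel:
    """Linkage-density model for a cohort of weekly symptom series.

    Parameters
    ----------
    data
        Tidy frame ``patient_id, week, symptom, value`` (the symptom-scale
        dialect written by :mod:`sldnet.scales`), or a list of
        :class:`~sldnet.scales.SymptomSeries`.
    min_lag_rows, min_coefficients, min_weeks
        Data-sufficiency thresholds (defaults 4, 48, 3).
    detrend
        Remove a per-symptom linear trend before standardizing (sensitivity
        option; off by default).
    shrinkage
        Empirical-Bayes option: shrink each patient's pair coefficients
        toward the cohort mean for that pair with reliability weights before
        averaging (off by default; the default estimator is transparent
        per-patient OLS).
    """

    def __init__(
        self,
        data,
        *,
        min_lag_rows: int = MIN_LAG_ROWS,
        min_coefficients: int = MIN_COEFFICIENTS,
        min_weeks: int = MIN_WEEKS,
        detrend: bool = False,
        shrinkage: bool = False,
    ):
        if isinstance(data, pd.DataFrame):
            self.series = series_from_long(data)
        else:
            self.series = list(data)
        self.min_lag_rows = min_lag_rows
        self.min_coefficients = min_coefficients
        self.min_weeks = min_weeks
        self.detrend = detrend
        self.shrinkage = shrinkage

    @classmethod
    def from_items(cls, items: pd.DataFrame, scale_map=None, min_items: int = 1, **kwargs):
        from .scales import score_cohort

        return cls(score_cohort(items, scale_map, min_items=min_items), **kwargs)

    def fit(self) -> "SymptomLinkageResults":
        linkages = [
            compute_sld(
                s,
                min_lag_rows=self.min_lag_rows,
                min_coefficients=self.min_coefficients,
                min_weeks=self.min_weeks,
                detrend=self.detrend,
            )
            for s in sorted(self.series, key=lambda s: s.patient_id)
        ]
        if self.shrinkage:
            linkages = _apply_shrinkage(linkages, self.min_coefficients)
        return SymptomLinkageResults(linkages, model=self)


def _apply_shrinkage(linkages: list[PatientLinkage], min_coefficients: int) -> list[PatientLinkage]:
    """Method-of-moments empirical-Bayes shrinkage toward per-pair cohort means."""
    table: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
    for i, pl in enumerate(linkages):
        for c in pl.coefficients:
            table.setdefault((c.source, c.target), []).append((i, c.beta2, c.se_beta2))
    post: dict[tuple[str, str], dict[int, float]] = {}
    for key, rows in table.items():
        betas = np.array([r[1] for r in rows])
        ses = np.array([r[2] for r in rows])
        ses = np.where(np.isfinite(ses), ses, np.nanmedian(ses))
        mu = betas.mean()
        var_b = max(betas.var(ddof=1) - np.mean(ses**2), 0.0) if len(betas) > 1 else 0.0
        w = var_b / (var_b + ses**2) if var_b > 0 else np.zeros_like(ses)
        post[key] = {rows[i][0]: float(mu + w[i] * (betas[i] - mu)) for i in range(len(rows))}
    out = []
    for i, pl in enumerate(linkages):
        if not pl.coefficients:
            out.append(pl)
            continue
        new_coeffs = [
            LaggedPairResult(
                source=c.source,
                target=c.target,
                beta2=post[(c.source, c.target)][i],
                beta1=c.beta1,
                beta0=c.beta0,
                se_beta2=c.se_beta2,
                n_lag_rows=c.n_lag_rows,
            )
            for c in pl.coefficients
        ]
        reliable = len(new_coeffs) >= min_coefficients
        out.append(
            PatientLinkage(
                patient_id=pl.patient_id,
                sld=float(np.mean([c.beta2 for c in new_coeffs])) if reliable else float("nan"),
                grand_mean=pl.grand_mean,
                grand_sd=pl.grand_sd,
                n_weeks_used=pl.n_weeks_used,
                n_coefficients=len(new_coeffs),
                eligible=pl.eligible,
                sld_reliable=reliable,
                coefficients=new_coeffs,
            )
        )
    return out


class SymptomLinkageResults:
    """Per-patient linkage estimates plus cohort-level reliability."""

    def __init__(self, linkages: list[PatientLinkage], model: SymptomLinkageModel | None = None):
        self.linkages = linkages
        self.model = model

    @property
    def patient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": pl.patient_id,
                    "sld": pl.sld,
                    "grand_mean": pl.grand_mean,
                    "grand_sd": pl.grand_sd,
                    "n_weeks_used": pl.n_weeks_used,
                    "n_coefficients": pl.n_coefficients,
                    "eligible": pl.eligible,
                    "sld_reliable": pl.sld_reliable,
                }
                for pl in self.linkages
            ]
        )

    @property
    def coefficients(self) -> pd.DataFrame:
        frames = [pl.coefficient_frame() for pl in self.linkages if pl.coefficients]
        if not frames:
            return pd.DataFrame(
                columns=["patient_id", "j", "k", "beta2", "se_beta2", "n_lag_rows"]
            )
        return pd.concat(frames, ignore_index=True)

    @property
    def n_patients(self) -> int:
        return len(self.linkages)

    @property
    def n_eligible(self) -> int:
        return sum(pl.eligible for pl in self.linkages)

    @property
    def alpha(self) -> float:
        """Cronbach's alpha treating the 72 pair coefficients as items."""
        coef = self.coefficients
        if coef.empty:
            raise ReliabilityUndefinedError("no coefficients")
        wide = coef.pivot_table(
            index="patient_id", columns=["j", "k"], values="beta2"
        )
        return cronbach_alpha(wide)

    def edge_matrix(self, patient_ids=None) -> pd.DataFrame:
        """Mean cross-lag coefficient matrix (rows: source j, cols: target k).

        Restricted to ``patient_ids`` when given — e.g. responders vs
        non-responders for network-style displays.
        """
        coef = self.coefficients
        if patient_ids is not None:
            wanted = {str(p) for p in patient_ids}
            coef = coef[coef["patient_id"].isin(wanted)]
        mat = coef.pivot_table(index="j", columns="k", values="beta2", aggfunc="mean")
        return mat.reindex(index=list(SYMPTOMS), columns=list(SYMPTOMS))

    def summary(self) -> str:
        tab = self.patient_table
        el = tab[tab["eligible"]]
        lines = [
            "Symptom linkage density estimation",
            "=" * 44,
            f"patients: {self.n_patients}   eligible (>= {MIN_WEEKS} weeks): {self.n_eligible}",
            f"weeks used: mean {el['n_weeks_used'].mean():.1f} (SD {el['n_weeks_used'].std(ddof=1):.1f})",
            f"coefficients per patient: median {el['n_coefficients'].median():.0f} "
            f"(range {el['n_coefficients'].min()}-{el['n_coefficients'].max()})",
            f"SLD: mean {el['sld'].mean():.3f} (SD {el['sld'].std(ddof=1):.3f})",
            f"grand mean: {el['grand_mean'].mean():.3f} (SD {el['grand_mean'].std(ddof=1):.3f})",
            f"grand SD: {el['grand_sd'].mean():.3f} (SD {el['grand_sd'].std(ddof=1):.3f})",
        ]
        try:
            lines.append(f"SLD internal consistency (alpha over pairs): {self.alpha:.3f}")
        except ReliabilityUndefinedError:
            lines.append("SLD internal consistency: undefined")
        return "\n".join(lines)

    def to_patient_csv(self, path) -> None:
        self.patient_table.to_csv(path, index=False)

    def to_coefficient_csv(self, path) -> None:
        self.coefficients.to_csv(path, index=False)
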