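"""Predictive-validity models for symptom linkage density.

Three model families quantify whether SLD carries incremental information
about treatment outcome beyond a patient's overall symptom level and
variability (the grand mean and grand SD are always controlled):

* :class:`ResponseModel` — maximum-likelihood logistic regression of
  treatment response on grand mean, grand SD and SLD, with odds ratios scaled
  to a 1-SD difference in each predictor (``OR = exp(B * SD)``).
* :class:`EndpointModel` — linear regression of an end-of-treatment endpoint
  (social adjustment, therapy-skill ratings) on its own baseline plus the
  three patient-level summaries; reports standardized betas
  ``B * SD_x / SD_y``.
* :class:`FollowupModel` — repeated-measures mixed model of post-treatment
  psychiatric status ratings (PSR, 1-6, averaged into 4-month periods) among
  responders, with a patient random intercept, categorical period and
  continuation arm, and backward trimming of non-significant interaction
  families (three-way first, then two-ways, at alpha = .05).

Group contrasts are summarized by Cohen's d with pooled SD and by a
histogram-based overlapping coefficient of the SLD distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import SldnetError, ZeroVarianceError

DEFAULT_PREDICTORS = ("grand_mean", "grand_sd", "sld")


def classify_response(exit_hrsd, mde_at_exit, threshold: int = 12):
    """Treatment response: no major depressive episode and exit HRSD <= threshold.

    The threshold is 12 under the primary-sample convention and 9 under the
    replication-sample convention. Accepts scalars or arrays.
    """
    exit_hrsd = np.asarray(exit_hrsd)
    if (exit_hrsd < 0).any():
        raise SldnetError("exit_hrsd must be non-negative")
    mde = np.asarray(mde_at_exit, dtype=bool)
    out = (~mde) & (exit_hrsd <= threshold)
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# logistic response model


class ResponseModel:
    """Logistic regression of response on patient-level symptom summaries."""

    def __init__(self, data: pd.DataFrame, predictors=DEFAULT_PREDICTORS, outcome="responder"):
        cols = [outcome, *predictors]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise SldnetError(f"missing columns: {missing}")
        self.data = data.dropna(subset=cols).copy()
        self.predictors = list(predictors)
        self.outcome = outcome
        y = self.data[outcome].astype(float)
        if y.nunique() < 2:
            raise SldnetError("need at least one responder and one non-responder")

    def fit(self) -> "ResponseResults":
        X = sm.add_constant(self.data[self.predictors].astype(float), has_constant="add")
        y = self.data[self.outcome].astype(float)
        converged = True
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            # complete separation and similar failures: flagged, regularized fallback
            res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
            converged = False
        sds = self.data[self.predictors].std(ddof=1)
        return ResponseResults(res, sds, self, converged)


class ResponseResults:
    """Logistic fit with 1-SD-scaled odds ratios (Table-2-style report)."""

    def __init__(self, res, predictor_sds: pd.Series, model: ResponseModel, converged: bool):
        self._res = res
        self.predictor_sds = predictor_sds
        self.model = model
        self.converged = converged
        self.nobs = int(res.nobs) if hasattr(res, "nobs") else len(model.data)

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def scaled_or(self) -> pd.Series:
        """Odds ratio per 1 SD of each predictor: exp(B * SD)."""
        b = self.params[self.model.predictors]
        return np.exp(b * self.predictor_sds[self.model.predictors])

    def table(self) -> pd.DataFrame:
        rows = [{"term": "Intercept", "B": self.params["const"], "SE": self.bse["const"],
                 "p": np.nan, "scaled_or": np.nan}]
        for term in self.model.predictors:
            rows.append(
                {
                    "term": term,
                    "B": self.params[term],
                    "SE": self.bse[term],
                    "p": self.pvalues[term],
                    "scaled_or": self.scaled_or[term],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.table()
        lines = [
            "Logistic regression of treatment response",
            f"n = {self.nobs}, ML estimation, converged = {self.converged}",
            f"{'term':<24}{'B':>9}{'SE':>8}{'p':>8}{'OR/SD':>8}",
        ]
        for _, r in tab.iterrows():
            p = "" if np.isnan(r["p"]) else f"{r['p']:.3f}"
            orr = "" if np.isnan(r["scaled_or"]) else f"{r['scaled_or']:.2f}"
            lines.append(f"{r['term']:<24}{r['B']:>9.2f}{r['SE']:>8.2f}{p:>8}{orr:>8}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# linear endpoint model


class EndpointModel:
    """Linear regression of an end-of-treatment endpoint on baseline + summaries.

    Rows with a missing endpoint are dropped (likelihood-based tolerance of
    missing outcomes with complete predictors); at least ``min_cases``
    complete-predictor cases are required.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        endpoint: str,
        baseline: str,
        predictors=DEFAULT_PREDICTORS,
        min_cases: int = 10,
    ):
        self.endpoint = endpoint
        self.baseline = baseline
        self.predictors = [baseline, *predictors]
        cols = [endpoint, *self.predictors]
        self.data = data.dropna(subset=cols).copy()
        if len(self.data) < min_cases:
            raise SldnetError(
                f"need >= {min_cases} complete cases for {endpoint}, got {len(self.data)}"
            )

    def fit(self) -> "EndpointResults":
        X = sm.add_constant(self.data[self.predictors].astype(float), has_constant="add")
        y = self.data[self.endpoint].astype(float)
        sd_y = y.std(ddof=1)
        if sd_y == 0:
            raise ZeroVarianceError(f"outcome {self.endpoint} has zero variance")
        res = sm.OLS(y, X).fit()
        sds = self.data[self.predictors].std(ddof=1)
        return EndpointResults(res, sds, sd_y, self)


class EndpointResults:
    """Linear fit with standardized betas (Table-3-style report)."""

    def __init__(self, res, predictor_sds, outcome_sd, model: EndpointModel):
        self._res = res
        self.predictor_sds = predictor_sds
        self.outcome_sd = float(outcome_sd)
        self.model = model
        self.nobs = int(res.nobs)

    @property
    def params(self):
        return self._res.params

    @property
    def bse(self):
        return self._res.bse

    @property
    def pvalues(self):
        return self._res.pvalues

    @property
    def std_beta(self) -> pd.Series:
        b = self.params[self.model.predictors]
        return b * self.predictor_sds[self.model.predictors] / self.outcome_sd

    def table(self) -> pd.DataFrame:
        rows = [{"term": "Intercept", "B": self.params["const"], "SE": self.bse["const"],
                 "p": np.nan, "std_beta": np.nan}]
        for term in self.model.predictors:
            rows.append(
                {
                    "term": term,
                    "B": self.params[term],
                    "SE": self.bse[term],
                    "p": self.pvalues[term],
                    "std_beta": self.std_beta[term],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.table()
        lines = [
            f"Linear regression of {self.model.endpoint} (n = {self.nobs})",
            f"{'term':<28}{'B':>9}{'SE':>8}{'p':>8}{'beta':>8}",
        ]
        for _, r in tab.iterrows():
            p = "" if np.isnan(r["p"]) else f"{r['p']:.3f}"
            bstd = "" if np.isnan(r["std_beta"]) else f"{r['std_beta']:.2f}"
            lines.append(f"{r['term']:<28}{r['B']:>9.2f}{r['SE']:>8.2f}{p:>8}{bstd:>8}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# repeated-measures follow-up model


_TWOWAY_FAMILIES = ("sld:arm", "sld:period", "arm:period")


def _term_groups(exog_names: list[str]) -> dict[str, list[int]]:
    """Group design columns into interpretable term families."""
    groups: dict[str, list[int]] = {}
    for i, name in enumerate(exog_names):
        if name in ("Intercept", "const"):
            fam = "intercept"
        else:
            parts = name.split(":")
            keys = []
            for p in parts:
                if p.startswith("C(arm)"):
                    keys.append("arm")
                elif p.startswith("C(period)"):
                    keys.append("period")
                else:
                    keys.append(p)
            fam = ":".join(sorted(keys, key=lambda k: ("sld", "arm", "period").index(k)
                                  if k in ("sld", "arm", "period") else 99))
        groups.setdefault(fam, []).append(i)
    return groups


@dataclass
class TrimStep:
    family: str
    p: float
    removed: bool


class FollowupModel:
    """Mixed model of follow-up severity (PSR) among treatment responders.

    ``data`` is long with columns ``patient_id, period, psr, arm, grand_mean,
    grand_sd, sld``. Fixed effects: categorical arm and period, grand mean,
    grand SD, SLD, plus candidate arm x period, SLD x arm, SLD x period and
    SLD x arm x period interactions; random patient intercept (compound
    symmetry); maximum likelihood. Non-significant interaction families are
    trimmed (three-way first, then two-ways jointly evaluated and removed).
    """

    def __init__(self, data: pd.DataFrame, covariance: str = "random_intercept"):
        req = ["patient_id", "period", "psr", "arm", "grand_mean", "grand_sd", "sld"]
        missing = [c for c in req if c not in data.columns]
        if missing:
            raise SldnetError(f"missing columns: {missing}")
        if covariance not in ("random_intercept",):
            raise SldnetError(f"unsupported covariance structure: {covariance}")
        data = data.dropna(subset=req).copy()
        data["period"] = data["period"].astype(int)
        self.single_arm = data["arm"].nunique() < 2
        per_patient = data.groupby("patient_id")["period"].nunique()
        if per_patient.mean() < 2:
            raise SldnetError("need >= 2 follow-up periods per patient on average")
        self.data = data
        self.covariance = covariance

    def _formula(self, three_way: bool, twoways: tuple[str, ...]) -> str:
        terms = ["grand_mean", "grand_sd", "sld", "C(period)"]
        if not self.single_arm:
            terms.insert(3, "C(arm)")
        if not self.single_arm and "arm:period" in twoways:
            terms.append("C(arm):C(period)")
        if not self.single_arm and "sld:arm" in twoways:
            terms.append("sld:C(arm)")
        if "sld:period" in twoways:
            terms.append("sld:C(period)")
        if three_way and not self.single_arm:
            terms.append("sld:C(arm):C(period)")
        return "psr ~ " + " + ".join(terms)

    def _fit_formula(self, formula: str):
        import warnings

        md = smf.mixedlm(formula, self.data, groups=self.data["patient_id"])
        last = None
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", module="statsmodels")
            for method in (["lbfgs"], ["powell"], ["cg"]):
                try:
                    res = md.fit(reml=False, method=method, maxiter=200)
                except Exception:
                    continue
                if res.converged:
                    return res, True
                last = res
        return last, False

    @staticmethod
    def _family_p(res, family: str) -> float:
        groups = _term_groups(list(res.model.exog_names))
        idx = groups.get(family)
        if not idx:
            return float("nan")
        k_total = len(res.params)  # fixed + variance params
        L = np.zeros((len(idx), k_total))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        wt = res.wald_test(L, scalar=True)
        return float(wt.pvalue)

    def fit(self, trim: bool = True, alpha: float = 0.05) -> "FollowupResults":
        trim_log: list[TrimStep] = []
        twoways = tuple(f for f in _TWOWAY_FAMILIES
                        if not (self.single_arm and "arm" in f))
        three_way = not self.single_arm

        if trim and three_way:
            res, conv = self._fit_formula(self._formula(True, twoways))
            p3 = self._family_p(res, "sld:arm:period") if res is not None else float("nan")
            if res is None or not np.isfinite(p3) or p3 > alpha:
                trim_log.append(TrimStep("sld:arm:period", p3, removed=True))
                three_way = False
            else:
                trim_log.append(TrimStep("sld:arm:period", p3, removed=False))

        res, conv = self._fit_formula(self._formula(three_way, twoways))
        if trim and not three_way and twoways:
            keep = []
            for fam in twoways:
                p = self._family_p(res, fam) if res is not None else float("nan")
                removed = (not np.isfinite(p)) or p > alpha
                trim_log.append(TrimStep(fam, p, removed=removed))
                if not removed:
                    keep.append(fam)
            if tuple(keep) != twoways:
                twoways = tuple(keep)
                res, conv = self._fit_formula(self._formula(False, twoways))
        elif trim and three_way:
            # significant three-way: keep the full hierarchy
            pass

        return FollowupResults(res, self, conv, trim_log,
                               retained=dict(three_way=three_way, twoways=twoways))


class FollowupResults:
    """Trimmed mixed-model fit with term-level F-type tests (Table-4 style)."""

    def __init__(self, res, model: FollowupModel, converged: bool,
                 trim_log: list[TrimStep], retained: dict):
        self._res = res
        self.model = model
        self.converged = bool(converged and res is not None)
        self.trim_log = trim_log
        self.retained = retained
        self.nobs = int(res.nobs) if res is not None else 0
        self.n_patients = int(model.data["patient_id"].nunique())
        d = model.data
        self._sds = {
            "sld": d.groupby("patient_id")["sld"].first().std(ddof=1),
            "grand_mean": d.groupby("patient_id")["grand_mean"].first().std(ddof=1),
            "grand_sd": d.groupby("patient_id")["grand_sd"].first().std(ddof=1),
            "psr": d["psr"].std(ddof=1),
        }

    @property
    def params(self):
        return self._res.params

    @property
    def fe_params(self):
        return self._res.fe_params

    @property
    def pvalues(self):
        return self._res.pvalues

    def std_beta(self, term: str) -> float:
        """Standardized beta: B * SD_predictor / raw SD of PSR."""
        return float(self.fe_params[term] * self._sds[term] / self._sds["psr"])

    def family_test(self, family: str) -> tuple[float, int, int, float]:
        """(F, df_num, df_den, p) for a term family via a joint Wald test."""
        groups = _term_groups(list(self._res.model.exog_names))
        idx = groups.get(family)
        if not idx:
            return (float("nan"), 0, 0, float("nan"))
        k_total = len(self._res.params)
        L = np.zeros((len(idx), k_total))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        wt = self._res.wald_test(L, scalar=True)
        q = len(idx)
        ddf = max(self.n_patients - len(self._res.fe_params), 1)
        F = float(wt.statistic) / q
        p = float(stats.f.sf(F, q, ddf))
        return (F, q, ddf, p)

    def anova_table(self) -> pd.DataFrame:
        groups = _term_groups(list(self._res.model.exog_names))
        rows = []
        for fam in groups:
            if fam == "intercept":
                continue
            F, q, ddf, p = self.family_test(fam)
            row = {"term": fam, "df_num": q, "df_den": ddf, "F": F, "p": p}
            if fam in ("sld", "grand_mean", "grand_sd"):
                row["std_beta"] = self.std_beta(fam)
            else:
                row["std_beta"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.anova_table()
        lines = [
            "Repeated-measures mixed model of follow-up PSR (responders)",
            f"n obs = {self.nobs}, patients = {self.n_patients}, ML, "
            f"random patient intercept, converged = {self.converged}",
            f"{'term':<18}{'df':>9}{'F':>8}{'p':>8}{'beta':>8}",
        ]
        for _, r in tab.iterrows():
            beta = "" if np.isnan(r["std_beta"]) else f"{r['std_beta']:.2f}"
            lines.append(
                f"{r['term']:<18}{int(r['df_num']):>4},{int(r['df_den']):>4}"
                f"{r['F']:>8.2f}{r['p']:>8.3f}{beta:>8}"
            )
        if self.trim_log:
            lines.append("trimming: " + "; ".join(
                f"{t.family} (p={t.p:.3f}, {'removed' if t.removed else 'kept'})"
                for t in self.trim_log
            ))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# effect sizes and distribution overlap


def effect_size_d(x1, x0) -> float:
    """Cohen's d with pooled sample SD (group 1 minus group 0)."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    x1, x0 = x1[np.isfinite(x1)], x0[np.isfinite(x0)]
    if len(x1) < 2 or len(x0) < 2:
        raise SldnetError("need >= 2 values per group")
    n1, n0 = len(x1), len(x0)
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2)
    if sp2 == 0:
        raise ZeroVarianceError("zero pooled SD")
    return float((x1.mean() - x0.mean()) / np.sqrt(sp2))


@dataclass
class OverlapResult:
    """Histogram-based overlapping coefficient of two distributions."""

    overlap: float
    bin_edges: np.ndarray
    props_1: np.ndarray
    props_0: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "prop_group1": self.props_1,
                "prop_group0": self.props_0,
            }
        )

    def plot(self, ax=None, labels=("group 1", "group 0")):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        width = np.diff(self.bin_edges)
        ax.bar(self.bin_edges[:-1], self.props_1, width=width, align="edge",
               alpha=0.5, label=labels[0])
        ax.bar(self.bin_edges[:-1], self.props_0, width=width, align="edge",
               alpha=0.5, label=labels[1])
        ax.set_xlabel("SLD")
        ax.set_ylabel("proportion")
        ax.legend()
        return ax


def distribution_overlap(x1, x0, bins=None) -> OverlapResult:
    """Overlapping coefficient estimated on a shared histogram binning.

    For two normals with equal SD separated by Cohen's d the population value
    is 2 * Phi(-d / 2).
    """
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    x1, x0 = x1[np.isfinite(x1)], x0[np.isfinite(x0)]
    if len(x1) < 2 or len(x0) < 2:
        raise SldnetError("need >= 2 values per group")
    combined = np.concatenate([x1, x0])
    if bins is None:
        bins = np.histogram_bin_edges(combined, bins="auto")
    elif np.isscalar(bins):
        bins = np.histogram_bin_edges(combined, bins=int(bins))
    c1, _ = np.histogram(x1, bins=bins)
    c0, _ = np.histogram(x0, bins=bins)
    p1 = c1 / c1.sum()
    p0 = c0 / c0.sum()
    return OverlapResult(
        overlap=float(np.minimum(p1, p0).sum()),
        bin_edges=np.asarray(bins),
        props_1=p1,
        props_0=p0,
    )


def overlap_normal(d: float) -> float:
    """Closed-form overlapping coefficient for equal-variance normals."""
    return float(2 * stats.norm.cdf(-abs(d) / 2))
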