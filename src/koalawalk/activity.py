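"""Diel-cycle models and energetic comparisons over behaviour bins.

The 24 h periodicity of activity (VeDBA_max) and of behaviour proportions
is modelled with a cyclic smooth over hour-of-day plus random intercepts
for individuals. The smooth is a truncated Fourier (harmonic) basis —
sine/cosine pairs of the 24 h fundamental — which is periodic by
construction, fitted as a linear mixed model. Energetic differences among
behaviour categories are assessed non-parametrically (Kruskal–Wallis, then
pairwise Wilcoxon rank-sum with Benjamini–Hochberg correction) on
log-transformed per-bin VeDBA_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .labels import WALKING

PERIOD_H = 24.0


def harmonic_basis(hours: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Design columns [1, sin(k w h), cos(k w h)] for k = 1..n_harmonics."""
    hours = np.asarray(hours, dtype=float)
    w = 2.0 * np.pi / PERIOD_H
    cols = [np.ones_like(hours)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(k * w * hours))
        cols.append(np.cos(k * w * hours))
    return np.column_stack(cols)


def _aggregate_hourly(bins: pd.DataFrame, response: str) -> pd.DataFrame:
    """Mean response per (individual, date, hour); hour centred on :30."""
    grp = (
        bins.groupby(["individual_id", "date", "hour"], sort=True)[response]
        .mean()
        .reset_index()
    )
    grp["hour_c"] = grp["hour"] + 0.5
    return grp.rename(columns={response: "y"})


@dataclass
class CyclicActivityResults:
    """Fitted cyclic smooth: population curve, uncertainty, diagnostics."""

    params: np.ndarray
    cov_params: np.ndarray
    n_harmonics: int
    residual_sd: float
    random_intercepts: bool
    group_var: float
    r_squared: float
    n_obs: int
    response: str
    link: str = "identity"  # "identity" | "logit"
    smooth_edf: float = 0.0

    def _design(self, hours) -> np.ndarray:
        return harmonic_basis(np.atleast_1d(hours), self.n_harmonics)

    def predict(self, hours) -> np.ndarray:
        """Population-level prediction at the given hours of day."""
        eta = self._design(hours) @ self.params
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def predict_se(self, hours) -> np.ndarray:
        x = self._design(hours)
        var = np.einsum("ij,jk,ik->i", x, self.cov_params, x)
        se = np.sqrt(np.maximum(var, 0.0))
        if self.link == "logit":
            p = self.predict(hours)
            se = se * p * (1.0 - p)  # delta method
        return se

    def hourly_table(self, step_h: float = 1.0,
                     interval: str = "ci") -> pd.DataFrame:
        """Hourly predictions with a ribbon: 95% CI ('ci') or +/- 1 residual
        SD ('residual_sd')."""
        hours = np.arange(0.0, 24.0 + 1e-9, step_h)
        mean = self.predict(hours)
        if interval == "residual_sd":
            half = self.residual_sd
        else:
            half = 1.96 * self.predict_se(hours)
        return pd.DataFrame(
            {"hour": hours, "mean": mean, "lower": mean - half,
             "upper": mean + half}
        )

    @property
    def peak_hour(self) -> float:
        grid = np.arange(0.0, 24.0, 0.05)
        return float(grid[np.argmax(self.predict(grid))])

    def summary(self) -> str:
        lines = [
            f"Cyclic diel model of {self.response} "
            f"({self.n_harmonics} harmonic pairs, link={self.link})",
            f"  n obs (individual-day-hours): {self.n_obs}",
            f"  random intercepts: {self.random_intercepts} "
            f"(group var {self.group_var:.4g})",
            f"  smooth edf: {self.smooth_edf:.1f}",
            f"  residual SD: {self.residual_sd:.4g}",
            f"  variance explained (R^2): {self.r_squared:.3f}",
            f"  peak hour: {self.peak_hour:.2f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, interval: str = "ci"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.hourly_table(0.25, interval=interval)
        ax.plot(tab["hour"], tab["mean"], lw=2)
        ax.fill_between(tab["hour"], tab["lower"], tab["upper"], alpha=0.3)
        ax.set_xlabel("hour of day")
        ax.set_ylabel(self.response)
        ax.set_xlim(0, 24)
        return ax


class CyclicActivityModel:
    """Cyclic smooth of a bin-level response over hour-of-day with random
    intercepts per individual.

    Data are aggregated to (individual, date, hour) means before fitting,
    which keeps the mixed model well-conditioned at full deployment sizes.
    """

    def __init__(self, bins: pd.DataFrame, response: str = "vedba_max_mean",
                 n_harmonics: int = 4, link: str = "identity"):
        self.response = response
        self.n_harmonics = n_harmonics
        self.link = link
        self.data = _aggregate_hourly(bins, response)
        if link == "logit":
            n_per_hour = 180.0  # 20 s bins in an hour
            eps = 0.5 / n_per_hour
            p = self.data["y"].clip(0, 1)
            self.data["y"] = np.log((p + eps) / (1 - p + eps))
        self.n_groups = self.data["individual_id"].nunique()

    def fit(self) -> CyclicActivityResults:
        y = self.data["y"].to_numpy(dtype=float)
        hours = self.data["hour_c"].to_numpy()
        # the harmonic design needs 2K+1 distinct hour values to be of
        # full rank; degrade gracefully on sparse diel coverage
        n_distinct = len(np.unique(hours))
        n_harm = min(self.n_harmonics, max(0, (n_distinct - 1) // 2))
        if n_harm < self.n_harmonics:
            warnings.warn(
                f"only {n_distinct} distinct hours covered; using "
                f"{n_harm} harmonic pairs")
        x = harmonic_basis(hours, n_harm)
        single = self.n_groups < 2
        if single:
            warnings.warn("single individual: fitting without random intercepts")
        rand = False
        if single or np.var(y) < 1e-14 or n_harm == 0:
            res = sm.OLS(y, x).fit()
            params, cov = res.params, res.cov_params()
            resid, group_var = y - x @ params, 0.0
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = MixedLM(
                        y, x, groups=self.data["individual_id"]).fit(reml=True)
                params = np.asarray(res.fe_params)
                cov = np.asarray(res.cov_params())[: len(params), : len(params)]
                resid = y - x @ params
                group_var = float(np.asarray(res.cov_re)[0, 0])
                rand = True
            except np.linalg.LinAlgError:
                warnings.warn("mixed fit singular; falling back to OLS")
                res = sm.OLS(y, x).fit()
                params, cov = res.params, res.cov_params()
                resid, group_var = y - x @ params, 0.0
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        # unpenalised smooth: edf = number of non-negligible harmonic terms
        scale = np.abs(params[1:]) / (np.std(y) + 1e-12)
        edf = 1.0 + float((scale > 1e-8).sum())
        return CyclicActivityResults(
            params=np.asarray(params), cov_params=np.asarray(cov),
            n_harmonics=n_harm,
            residual_sd=float(np.std(resid)),
            random_intercepts=rand, group_var=group_var,
            r_squared=max(r2, 0.0), n_obs=len(y), response=self.response,
            link=self.link, smooth_edf=edf,
        )


def fit_cyclic_activity(bins: pd.DataFrame, response: str = "vedba_max_mean",
                        n_harmonics: int = 4) -> CyclicActivityResults:
    """Diel activity curve (default: VeDBA_max) with individual intercepts."""
    hours = bins.groupby(["individual_id", "date", "hour"]).ngroups
    if hours < 48:
        warnings.warn("less than 48 h of coverage; diel fit may be unstable")
    return CyclicActivityModel(bins, response, n_harmonics).fit()


def fit_walking_curve(bins: pd.DataFrame,
                      n_harmonics: int = 3) -> CyclicActivityResults:
    """Diel curve of the walking proportion (empirical-logit scale).

    The response is the per (individual, date, hour) proportion of 20 s
    bins labelled Walking; predictions are returned on the proportion scale.
    """
    usable = bins.loc[~bins["is_gap"] & (bins["label"] != "")].copy()
    if not (usable["label"] == WALKING).any():
        raise ValueError("no Walking bins present")
    usable["walk"] = (usable["label"] == WALKING).astype(float)
    return CyclicActivityModel(
        usable, response="walk", n_harmonics=n_harmonics, link="logit"
    ).fit()


# ---------------------------------------------------------------------------
# distributional comparison of VeDBA across behaviours

@dataclass
class RankTestResult:
    """Kruskal–Wallis omnibus plus BH-corrected pairwise Wilcoxon tests."""

    statistic: float
    df: int
    pvalue: float
    pairwise: pd.DataFrame
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        lines = [
            f"Kruskal–Wallis H = {self.statistic:.2f}, "
            f"df = {self.df}, p = {self.pvalue:.3g}",
            self.pairwise.to_string(index=False),
        ]
        return "\n".join(lines)


def compare_vedba(bins: pd.DataFrame,
                  response: str = "vedba_max_mean") -> RankTestResult:
    """Compare per-bin VeDBA_max across behaviour categories.

    Values are log-transformed (right skew); the omnibus Kruskal–Wallis test
    is followed by all pairwise two-sided Wilcoxon rank-sum tests with
    Benjamini–Hochberg adjustment. Mid-ranks handle ties.
    """
    usable = bins.loc[(bins["label"] != "") & np.isfinite(bins[response])]
    groups = {
        name: np.log(grp[response].to_numpy() + 1e-12)
        for name, grp in usable.groupby("label", sort=True)
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 categories with >= 2 observations")
    names = list(groups)
    h, p = stats.kruskal(*groups.values())

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.mannwhitneyu(groups[names[i]], groups[names[j]],
                                     alternative="two-sided",
                                     method="asymptotic")
            rows.append({"group1": names[i], "group2": names[j],
                         "statistic": float(res.statistic),
                         "p_raw": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]

    summary = pd.DataFrame(
        {
            "category": names,
            "n": [len(groups[n]) for n in names],
            "median": [float(np.median(np.exp(groups[n]))) for n in names],
            "iqr_low": [float(np.percentile(np.exp(groups[n]), 25)) for n in names],
            "iqr_high": [float(np.percentile(np.exp(groups[n]), 75)) for n in names],
        }
    )
    return RankTestResult(
        statistic=float(h), df=len(names) - 1, pvalue=float(p),
        pairwise=pairwise, group_summary=summary,
    )


# ---------------------------------------------------------------------------
# covariate effects on daily walking time

@dataclass
class WalkingCovariateResults:
    """Fixed-effect summary of the daily-walking mixed model."""

    effects: pd.DataFrame  # coef, se, stat (Wald z^2 ~ F-type, df=1), p
    group_var: float
    residual_var: float
    n_obs: int
    n_groups: int

    def summary(self) -> str:
        return (
            f"Daily walking minutes ~ sex + habitat + (1 | individual)\n"
            f"  n = {self.n_obs} animal-days, {self.n_groups} individuals\n"
            + self.effects.to_string()
        )


class WalkingCovariateModel:
    """Linear mixed model of daily walking minutes on sex and habitat with
    a random intercept per individual."""

    def __init__(self, budgets: pd.DataFrame, response: str = "minutes"):
        data = budgets.loc[budgets["category"] == WALKING].copy()
        if data.empty:
            raise ValueError("no Walking rows in the budgets")
        if float(np.var(data[response])) < 1e-14:
            raise ValueError("response has zero variance")
        self.data = data
        self.response = response

    def fit(self) -> WalkingCovariateResults:
        d = self.data
        y = d[self.response].to_numpy(dtype=float)
        x = np.column_stack(
            [
                np.ones(len(d)),
                (d["sex"].astype(str) == "M").astype(float),
                (d["habitat"].astype(str) == "linear").astype(float),
            ]
        )
        names = ["intercept", "sex[M]", "habitat[linear]"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, x, groups=d["individual_id"]).fit(reml=True)
        coef = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        z = coef / se
        # sex and habitat vary between individuals, so the reference
        # distribution is F(1, n_groups - p) — the between-animal df —
        # rather than the anti-conservative normal approximation
        n_groups = d["individual_id"].nunique()
        df_denom = max(1, n_groups - x.shape[1])
        effects = pd.DataFrame(
            {
                "coef": coef,
                "se": se,
                "stat": z**2,  # Wald F-type statistic, df = (1, df_denom)
                "p": stats.f.sf(z**2, 1, df_denom),
            },
            index=names,
        )
        return WalkingCovariateResults(
            effects=effects,
            group_var=float(np.asarray(res.cov_re)[0, 0]),
            residual_var=float(res.scale),
            n_obs=len(d),
            n_groups=n_groups,
        )


def walking_covariate_test(budgets: pd.DataFrame) -> WalkingCovariateResults:
    """Test sex and habitat effects on daily walking minutes."""
    return WalkingCovariateModel(budgets).fit()
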