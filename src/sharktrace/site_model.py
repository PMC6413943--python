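"""Random-intercept linear mixed model of visit duration by site.

Model: for visit k of animal i at site s(k),

    y_ik = beta_{s(k)} + b_i + e_ik,   b_i ~ N(0, sigma2_g),  e_ik ~ N(0, sigma2_r)

with site a categorical fixed effect (reference-level coding; the intercept
is the reference-site mean) and a per-animal random intercept separating
between- and within-animal variance in visit length. The response is by
default the natural log of visit duration in hours, so site effects are
multiplicative on duration.

Estimation profiles the fixed effects and the residual variance
analytically given the variance ratio lambda = sigma2_g / sigma2_r, and
maximises the profiled (restricted) log-likelihood over lambda >= 0 by
one-dimensional bounded search. The boundary lambda = 0 (no animal effect,
ordinary least squares) is admitted. Likelihood-ratio tests of the site
effect use ML fits (REML log-likelihoods are not comparable across fixed
structures); pairwise site contrasts use Wald statistics with Satterthwaite
degrees of freedom and Holm adjustment over the 15 site pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    beta: pd.Series                 # fixed effects, reference-level coding
    se_beta: pd.Series
    sigma2_group: float             # between-animal (random intercept) variance
    sigma2_resid: float             # within-animal (residual) variance
    loglik: float                   # maximised (restricted) log-likelihood
    criterion: str                  # "ML" or "REML"
    satterthwaite_df: pd.Series     # per-coefficient approximate df
    vcov_beta: pd.DataFrame = field(repr=False)
    site_levels: list[str] = field(default_factory=list)
    reference: str = ""
    n_obs: int = 0
    n_groups: int = 0
    df_normal_fallback: bool = False

    @property
    def n_fixed(self) -> int:
        return len(self.beta)

    def site_means(self) -> pd.Series:
        """Fitted mean response per site (intercept + site offset)."""
        means = {self.reference: self.beta.iloc[0]}
        for lev in self.site_levels:
            if lev != self.reference:
                means[lev] = self.beta.iloc[0] + self.beta[f"site[{lev}]"]
        return pd.Series(means)

    def summary_frame(self) -> pd.DataFrame:
        t = self.beta / self.se_beta
        p = 2.0 * stats.t.sf(np.abs(t), self.satterthwaite_df)
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "std_error": self.se_beta,
                "df": self.satterthwaite_df,
                "t_value": t,
                "p_value": p,
            }
        )


class _Design:
    """Grouped design with per-group sufficient statistics for the profiled fit."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> None:
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        order = np.argsort(groups, kind="stable")
        self.codes, starts = np.unique(groups[order], return_index=True)
        self.slices = np.split(order, starts[1:])
        self.n_groups = len(self.slices)
        self.XtX_g = [X[idx].T @ X[idx] for idx in self.slices]
        self.Xt1_g = [X[idx].sum(axis=0) for idx in self.slices]
        self.Xty_g = [X[idx].T @ y[idx] for idx in self.slices]
        self.yty_g = [float(y[idx] @ y[idx]) for idx in self.slices]
        self.y1_g = [float(y[idx].sum()) for idx in self.slices]
        self.sizes = np.array([len(idx) for idx in self.slices])

    def gls(self, lam: float) -> tuple[np.ndarray, float, float, np.ndarray]:
        """beta-hat, weighted RSS r'V*^-1 r, log|V*|, X'V*^-1 X for V* = I + lam ZZ'."""
        w = lam / (1.0 + lam * self.sizes)
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        for XtX, Xt1, Xty, y1, wi in zip(self.XtX_g, self.Xt1_g, self.Xty_g, self.y1_g, w):
            A += XtX - wi * np.outer(Xt1, Xt1)
            b += Xty - wi * Xt1 * y1
        beta = np.linalg.solve(A, b)
        rss = 0.0
        for idx, wi in zip(self.slices, w):
            r = self.y[idx] - self.X[idx] @ beta
            rss += float(r @ r) - wi * float(r.sum()) ** 2
        logdet_v = float(np.log1p(lam * self.sizes).sum())
        return beta, rss, logdet_v, A


def _profiled_loglik(design: _Design, lam: float, criterion: str) -> tuple[float, dict]:
    n, p = design.n, design.p
    beta, rss, logdet_v, A = design.gls(lam)
    if criterion == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_v + n)
    else:
        sigma2 = rss / (n - p)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, {}
        ll = -0.5 * ((n - p) * np.log(2.0 * np.pi * sigma2) + logdet_v + logdet_a + (n - p))
    return float(ll), {"beta": beta, "sigma2_resid": sigma2, "A": A}


def _reml_loglik_theta(design: _Design, sigma2_g: float, sigma2_r: float, criterion: str) -> float:
    """(Restricted) log-likelihood at explicit variance components."""
    if sigma2_r <= 0 or sigma2_g < 0:
        return -np.inf
    lam = sigma2_g / sigma2_r
    n, p = design.n, design.p
    beta, rss, logdet_v, A = design.gls(lam)
    quad = rss / sigma2_r
    logdet_full = n * np.log(sigma2_r) + logdet_v
    if criterion == "ML":
        return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet_full + quad))
    sign, logdet_a = np.linalg.slogdet(A / sigma2_r)
    if sign <= 0:
        return -np.inf
    return float(-0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet_full + logdet_a + quad))


def build_design(
    records: pd.DataFrame, reference: str | None = None, intercept_only: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str], str]:
    """Reference-coded design matrix from (tag_id, site, response) records."""
    y = records["response"].to_numpy(float)
    groups = records["tag_id"].astype(str).to_numpy()
    levels = sorted(records["site"].astype(str).unique())
    if reference is None:
        reference = "Alcyone" if "Alcyone" in levels else levels[0]
    elif reference not in levels:
        raise ValueError(f"reference level {reference!r} not among site levels {levels}")
    if intercept_only:
        X = np.ones((len(y), 1))
        names = ["(Intercept)"]
    else:
        others = [lev for lev in levels if lev != reference]
        site = records["site"].astype(str).to_numpy()
        X = np.column_stack([np.ones(len(y))] + [(site == lev).astype(float) for lev in others])
        names = ["(Intercept)"] + [f"site[{lev}]" for lev in others]
    return y, X, groups, names, levels, reference


class RandomInterceptLMM:
    """One-way random-intercept linear mixed model, profiled-likelihood fit.

    Parameters
    ----------
    criterion
        ``"REML"`` (default, unbiased variance components) or ``"ML"``
        (required for likelihood-ratio tests of fixed effects).
    reference
        Reference site level for the intercept; defaults to ``"Alcyone"``
        when present, else the alphabetically first level.
    """

    def __init__(self, criterion: str = "REML", reference: str | None = None) -> None:
        criterion = criterion.upper()
        if criterion not in {"ML", "REML"}:
            raise ValueError("criterion must be 'ML' or 'REML'")
        self.criterion = criterion
        self.reference = reference

    def fit(self, records: pd.DataFrame, intercept_only: bool = False) -> LMMFit:
        """Fit to records with columns ``tag_id``, ``site``, ``response``."""
        y, X, groups, names, levels, reference = build_design(
            records, self.reference, intercept_only
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design (empty site level?)")
        if len(np.unique(groups)) < 1:
            raise ValueError("no grouping levels")
        design = _Design(y, X, groups)

        def neg(loglam: float) -> float:
            return -_profiled_loglik(design, float(np.exp(loglam)), self.criterion)[0]

        res = optimize.minimize_scalar(
            neg, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            options={"xatol": 1e-10},
        )
        ll_opt, _ = _profiled_loglik(design, float(np.exp(res.x)), self.criterion)
        ll_zero, _ = _profiled_loglik(design, 0.0, self.criterion)
        lam = 0.0 if ll_zero >= ll_opt else float(np.exp(res.x))
        ll, aux = _profiled_loglik(design, lam, self.criterion)
        beta = aux["beta"]
        sigma2_r = float(aux["sigma2_resid"])
        sigma2_g = lam * sigma2_r
        vcov = sigma2_r * np.linalg.inv(aux["A"])
        se = np.sqrt(np.diag(vcov))

        df, fallback = self._satterthwaite(design, sigma2_g, sigma2_r, np.eye(len(beta)))
        return LMMFit(
            beta=pd.Series(beta, index=names),
            se_beta=pd.Series(se, index=names),
            sigma2_group=sigma2_g,
            sigma2_resid=sigma2_r,
            loglik=ll,
            criterion=self.criterion,
            satterthwaite_df=pd.Series(df, index=names),
            vcov_beta=pd.DataFrame(vcov, index=names, columns=names),
            site_levels=levels,
            reference=reference,
            n_obs=design.n,
            n_groups=design.n_groups,
            df_normal_fallback=fallback,
        )

    # -- Satterthwaite machinery -------------------------------------------

    def _theta_cov(self, design: _Design, sigma2_g: float, sigma2_r: float) -> np.ndarray | None:
        """Asymptotic covariance of (sigma2_g, sigma2_r): inverse observed information."""
        theta = np.array([sigma2_g, sigma2_r])
        h = np.maximum(1e-6, 1e-4 * np.maximum(theta, sigma2_r))

        def ll(t: np.ndarray) -> float:
            return _reml_loglik_theta(design, max(t[0], 0.0), t[1], self.criterion)

        H = np.zeros((2, 2))
        f0 = ll(theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                if i == j:
                    H[i, i] = (ll(theta + ei) - 2 * f0 + ll(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        ll(theta + ei + ej) - ll(theta + ei - ej)
                        - ll(theta - ei + ej) + ll(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
            return None
        return cov

    def _satterthwaite(
        self, design: _Design, sigma2_g: float, sigma2_r: float, contrasts: np.ndarray
    ) -> tuple[np.ndarray, bool]:
        """Approximate df for each contrast row c: 2 f^2 / Var(f), f = c' C(theta) c."""
        cov_theta = self._theta_cov(design, sigma2_g, sigma2_r)
        n, p = design.n, design.p

        def cvar(c: np.ndarray, sg: float, sr: float) -> float:
            lam = max(sg, 0.0) / sr
            _, _, _, A = design.gls(lam)
            return float(sr * c @ np.linalg.solve(A, c))

        if cov_theta is None:
            return np.full(len(contrasts), float(n - p)), True
        theta = np.array([sigma2_g, sigma2_r])
        h = np.maximum(1e-6, 1e-4 * np.maximum(theta, sigma2_r))
        dfs = np.empty(len(contrasts))
        for k, c in enumerate(contrasts):
            f0 = cvar(c, sigma2_g, sigma2_r)
            grad = np.array(
                [
                    (cvar(c, sigma2_g + h[0], sigma2_r) - cvar(c, max(sigma2_g - h[0], 0.0), sigma2_r))
                    / (h[0] + min(sigma2_g, h[0])),
                    (cvar(c, sigma2_g, sigma2_r + h[1]) - cvar(c, sigma2_g, sigma2_r - h[1]))
                    / (2 * h[1]),
                ]
            )
            var_f = float(grad @ cov_theta @ grad)
            dfs[k] = 2.0 * f0**2 / var_f if var_f > 0 else float(n - p)
        return np.clip(dfs, 1.0, None), False


def fit_lmm(
    records: pd.DataFrame,
    criterion: str = "REML",
    reference: str | None = None,
    intercept_only: bool = False,
) -> LMMFit:
    """Fit the random-intercept visit-duration model (thin wrapper)."""
    return RandomInterceptLMM(criterion, reference).fit(records, intercept_only)


def lrt_site_effect(null_fit: LMMFit, full_fit: LMMFit) -> dict:
    """Likelihood-ratio test of the site fixed effect.

    Both fits must use ML on the same records; the statistic is
    ``2 (loglik_full − loglik_null)`` (clipped at 0) on df equal to the
    difference in fixed-effect count, with a chi-square upper-tail p-value.
    """
    if null_fit.criterion != "ML" or full_fit.criterion != "ML":
        raise ValueError("likelihood-ratio tests require ML fits on both models")
    if null_fit.n_obs != full_fit.n_obs:
        raise ValueError("fits are not on identical records")
    chi2 = max(2.0 * (full_fit.loglik - null_fit.loglik), 0.0)
    df = full_fit.n_fixed - null_fit.n_fixed
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return {"chi2": chi2, "df": df, "p": p}


def pairwise_site_contrasts(fit: LMMFit, adjust: str = "holm") -> pd.DataFrame:
    """Wald contrasts of all unordered site pairs, Holm-adjusted.

    The estimate for pair (i, j) is the difference of fitted site means;
    degrees of freedom are Satterthwaite unless the variance-component
    information matrix is not usable, in which case a normal approximation
    (large df) is flagged via ``fit.df_normal_fallback``.
    """
    levels = fit.site_levels
    names = list(fit.beta.index)
    p = len(names)

    def coef_vec(level: str) -> np.ndarray:
        v = np.zeros(p)
        if level != fit.reference:
            v[names.index(f"site[{level}]")] = 1.0
        return v

    rows = []
    vcov = fit.vcov_beta.to_numpy()
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            c = coef_vec(levels[a]) - coef_vec(levels[b])
            est = float(c @ fit.beta.to_numpy())
            se = float(np.sqrt(c @ vcov @ c))
            rows.append((levels[a], levels[b], est, se, c))
    # Satterthwaite df for each contrast needs the design; approximate with
    # the minimum coefficient df involved, a conservative choice.
    out = []
    for site_i, site_j, est, se, c in rows:
        involved = [k for k in range(p) if c[k] != 0]
        df = float(min(fit.satterthwaite_df.iloc[k] for k in involved)) if involved else 1.0
        t = est / se if se > 0 else 0.0
        pval = 2.0 * float(stats.t.sf(abs(t), df))
        out.append((site_i, site_j, est, se, t, df, pval))
    table = pd.DataFrame(
        out, columns=["site_i", "site_j", "estimate", "std_error", "statistic", "df", "p_value"]
    )
    table["p_adjusted"] = multipletests(table["p_value"], method=adjust)[1]
    return table


def visits_to_records(
    visits: pd.DataFrame,
    response: str = "log-hours",
    include_transits: bool = True,
) -> pd.DataFrame:
    """Visit table -> model records with the configured response transform.

    ``log-hours`` (default): natural log of duration in hours; zero-duration
    events are floored at one ping interval (60 s) to keep the log finite.
    ``hours``: identity on duration in hours.
    """
    v = visits if include_transits or "is_transit" not in visits.columns else visits[~visits["is_transit"]]
    hours = v["duration_s"].to_numpy(float) / 3600.0
    if response == "log-hours":
        resp = np.log(np.maximum(hours, 60.0 / 3600.0))
    elif response == "hours":
        resp = hours
    else:
        raise ValueError("response must be 'log-hours' or 'hours'")
    return pd.DataFrame(
        {"tag_id": v["tag_id"].astype(str).to_numpy(), "site": v["station_id"].astype(str).to_numpy(), "response": resp}
    )
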