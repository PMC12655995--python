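"""Bayesian bivariate selection of promising accessions.

The model is a bivariate linear mixed model on the two yield-discriminant
descriptors, seed index (SI, g; higher is better) and pod index (PI, pods
per kg dry seed; lower is better)::

    y_is = mu + a_i + e_is,   a_i ~ N2(0, Sigma_a),   e_is ~ N2(0, Sigma_e)

with accession effects ``a_i`` and season-level residuals, fitted by a Gibbs
sampler with conjugate updates: Gaussian for the trait means and accession
effects, inverse-Wishart for both covariance matrices.  Priors are weakly
informative (inverse-Wishart, nu = 3, scale 0.01 * I) and configurable.

The Bayesian Yield Stability Index (BYSI) of an accession is the genotypic
value ``mu + a_i`` that the trait exceeds with 90% posterior probability
(the 10th posterior percentile) for higher-is-better traits, and the
mirrored 90th percentile (the value it stays below with 90% probability) for
lower-is-better traits.  An accession is promising when its BYSI_SI exceeds
the SI threshold *and* its BYSI_PI is below the PI threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from sklearn.base import BaseEstimator

DEFAULT_SI_MIN = 0.8
DEFAULT_PI_MAX = 23.5


def geweke_z(draws: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score between the first and last chain segments,
    with ESS-adjusted standard errors."""
    n = len(draws)
    a = draws[: max(int(first * n), 2)]
    b = draws[-max(int(last * n), 2):]

    def se(x):
        ess = float(az.ess(np.asarray(x)[None, :]))
        return np.sqrt(np.var(x, ddof=1) / max(ess, 1.0))

    denom = np.sqrt(se(a) ** 2 + se(b) ** 2)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


class BivariateGibbs(BaseEstimator):
    """Gibbs sampler for the bivariate accession-effects mixed model.

    Parameters
    ----------
    iterations : int
        Post-burn-in iterations.
    burnin : int
        Discarded initial iterations.
    thin : int
        Keep every ``thin``-th draw.
    prior_nu : float
        Inverse-Wishart prior degrees of freedom for both covariances.
    prior_scale : float
        Inverse-Wishart prior scale is ``prior_scale * I`` (the
        weakly-informative default mirroring "non-informative" settings).
    random_state : int
        RNG seed.

    Attributes (after ``fit``)
    --------------------------
    mu_draws_ : (S, 2) trait-mean draws; sigma_a_draws_, sigma_e_draws_ :
    (S, 2, 2); genotypic_draws_ : (S, n, 2) draws of ``mu + a_i``;
    accessions_ : index; diagnostics_ : DataFrame (ESS, Geweke z);
    converged_ : bool (False flags |z| > 3 on a variance parameter).
    """

    def __init__(
        self,
        iterations: int = 5000,
        burnin: int = 1000,
        thin: int = 2,
        prior_nu: float = 3.0,
        prior_scale: float = 0.01,
        random_state: int = 0,
    ):
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.prior_nu = prior_nu
        self.prior_scale = prior_scale
        self.random_state = random_state

    def fit(self, table: pd.DataFrame, y=None):
        """Fit from a long table with columns accession, SI, PI (one row per
        accession x season)."""
        if self.iterations < 5000:
            raise ValueError("iterations must be >= 5000 after burn-in")
        for c in ("accession", "SI", "PI"):
            if c not in table.columns:
                raise ValueError(f"table missing column {c!r}")
        acc, gidx = np.unique(table["accession"].to_numpy(), return_inverse=True)
        Y = table[["SI", "PI"]].to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise ValueError("NaN values in SI/PI table")
        n, N = len(acc), len(Y)
        m_i = np.bincount(gidx).astype(float)
        if np.mean(m_i >= 2) < 0.8:
            raise ValueError(
                ">= 80% of accessions need >= 2 observations (seasons)"
            )

        rng = np.random.default_rng(self.random_state)
        S0 = self.prior_scale * np.eye(2)
        nu0 = self.prior_nu

        # initialize from moments
        acc_means = np.vstack(
            [np.bincount(gidx, weights=Y[:, t]) for t in range(2)]
        ).T / m_i[:, None]
        mu = Y.mean(axis=0)
        Sigma_a = np.cov(acc_means.T) + 1e-6 * np.eye(2)
        resid0 = Y - acc_means[gidx]
        Sigma_e = np.cov(resid0.T) + 1e-6 * np.eye(2)
        a = acc_means - mu

        n_iter = self.burnin + self.iterations
        keep = np.zeros(n_iter, dtype=bool)
        keep[self.burnin :: self.thin] = True
        S = int(keep.sum())
        mu_draws = np.empty((S, 2))
        sa_draws = np.empty((S, 2, 2))
        se_draws = np.empty((S, 2, 2))
        g_draws = np.empty((S, n, 2))

        # per-accession sums of observations, grouped by replication count
        sums = np.vstack(
            [np.bincount(gidx, weights=Y[:, t]) for t in range(2)]
        ).T  # n x 2
        groups = {m: np.where(m_i == m)[0] for m in np.unique(m_i)}

        s_out = 0
        for it in range(n_iter):
            Se_inv = np.linalg.inv(Sigma_e)
            Sa_inv = np.linalg.inv(Sigma_a)
            # accession effects
            for m, ii in groups.items():
                P = m * Se_inv + Sa_inv
                L = cholesky(P, lower=True)
                Minv = np.linalg.inv(P)
                rhs = (sums[ii] - m * mu) @ Se_inv.T
                means = rhs @ Minv.T
                z = rng.standard_normal((len(ii), 2))
                Linv = solve_triangular(L, np.eye(2), lower=True)
                a[ii] = means + z @ Linv
            # trait means (flat prior)
            resid_mean = (Y - a[gidx]).mean(axis=0)
            Lmu = cholesky(Sigma_e / N, lower=True)
            mu = resid_mean + Lmu @ rng.standard_normal(2)
            # covariances
            Sa_post = S0 + a.T @ a
            Sigma_a = stats.invwishart.rvs(df=nu0 + n, scale=Sa_post,
                                           random_state=rng)
            E = Y - mu - a[gidx]
            Se_post = S0 + E.T @ E
            Sigma_e = stats.invwishart.rvs(df=nu0 + N, scale=Se_post,
                                           random_state=rng)
            if keep[it]:
                mu_draws[s_out] = mu
                sa_draws[s_out] = Sigma_a
                se_draws[s_out] = Sigma_e
                g_draws[s_out] = mu + a
                s_out += 1

        self.accessions_ = pd.Index(acc, name="accession")
        self.mu_draws_ = mu_draws
        self.sigma_a_draws_ = sa_draws
        self.sigma_e_draws_ = se_draws
        self.genotypic_draws_ = g_draws
        self.n_draws_ = S

        diag_params = {
            "mu_SI": mu_draws[:, 0],
            "mu_PI": mu_draws[:, 1],
            "sigma_a_SI": sa_draws[:, 0, 0],
            "sigma_a_PI": sa_draws[:, 1, 1],
            "sigma_a_cov": sa_draws[:, 0, 1],
            "sigma_e_SI": se_draws[:, 0, 0],
            "sigma_e_PI": se_draws[:, 1, 1],
        }
        rows = {}
        for name, d in diag_params.items():
            rows[name] = {
                "ess": float(az.ess(d[None, :])),
                "geweke_z": geweke_z(d),
            }
        self.diagnostics_ = pd.DataFrame(rows).T
        var_rows = self.diagnostics_.loc[
            [r for r in self.diagnostics_.index if r.startswith("sigma")]
        ]
        self.converged_ = bool((var_rows["geweke_z"].abs() <= 3.0).all())
        return self

    # -- posterior summaries ----------------------------------------------

    def posterior_correlation_(self) -> float:
        """Posterior mean of the accession-effect correlation."""
        sa = self.sigma_a_draws_
        r = sa[:, 0, 1] / np.sqrt(sa[:, 0, 0] * sa[:, 1, 1])
        return float(r.mean())

    def hpd(self, prob: float = 0.95) -> pd.DataFrame:
        """HPD intervals of the genotypic values, per accession and trait."""
        out = {}
        for t, trait in enumerate(("SI", "PI")):
            hdi = az.hdi(self.genotypic_draws_[None, :, :, t], hdi_prob=prob)
            out[f"{trait}_hpd_low"] = hdi[:, 0]
            out[f"{trait}_hpd_high"] = hdi[:, 1]
        return pd.DataFrame(out, index=self.accessions_)


def fit_bivariate(
    si_pi_table: pd.DataFrame,
    iterations: int = 5000,
    burnin: int = 1000,
    thin: int = 2,
    seed: int = 0,
    **kwargs,
) -> BivariateGibbs:
    """Fit the bivariate Gibbs model (thin wrapper over
    :class:`BivariateGibbs`)."""
    return BivariateGibbs(
        iterations=iterations, burnin=burnin, thin=thin, random_state=seed,
        **kwargs,
    ).fit(si_pi_table)


def bysi(
    model: BivariateGibbs, prob: float = 0.90, hpd_prob: float = 0.95
) -> pd.DataFrame:
    """Bayesian Yield Stability Index per accession.

    BYSI_SI is the posterior ``1 - prob`` quantile of the SI genotypic value
    (exceeded with probability ``prob``); BYSI_PI is the mirrored ``prob``
    quantile (not exceeded with probability ``prob``).  95% HPD intervals of
    the genotypic values are reported alongside.
    """
    if not 0.5 < prob < 1.0:
        raise ValueError("prob must be in (0.5, 1)")
    if model.n_draws_ < 1000:
        raise ValueError("need >= 1000 retained draws")
    g = model.genotypic_draws_  # S x n x 2
    out = pd.DataFrame(
        {
            "BYSI_SI": np.quantile(g[:, :, 0], 1.0 - prob, axis=0),
            "BYSI_PI": np.quantile(g[:, :, 1], prob, axis=0),
            "SI_median": np.median(g[:, :, 0], axis=0),
            "PI_median": np.median(g[:, :, 1], axis=0),
        },
        index=model.accessions_,
    )
    return out.join(model.hpd(prob=hpd_prob))


def gaussian_bysi(mean: float, sd: float, prob: float = 0.90) -> float:
    """Closed-form BYSI for a Gaussian posterior (higher-is-better trait):
    ``mean - z_prob * sd``."""
    return float(mean - stats.norm.ppf(prob) * sd)


@dataclass
class SelectionResult:
    table: pd.DataFrame
    si_min: float
    pi_max: float
    n_selected: int
    n_total: int
    excluded: list = field(default_factory=list)

    @property
    def selected_pct(self) -> float:
        return 100.0 * self.n_selected / self.n_total if self.n_total else 0.0

    @property
    def selected(self) -> list:
        return self.table.index[self.table["selected"]].tolist()


def select_promising(
    bysi_table: pd.DataFrame,
    si_min: float = DEFAULT_SI_MIN,
    pi_max: float = DEFAULT_PI_MAX,
) -> SelectionResult:
    """Bivariate threshold rule: an accession is promising iff
    ``BYSI_SI > si_min`` and ``BYSI_PI < pi_max``.

    Quadrants on the (PI, SI) plane are split at the thresholds:
    I = poor on both, II = favourable PI only, III = favourable on both
    (the selected region), IV = favourable SI only.  Accessions with a
    missing BYSI value are excluded with a flag.
    """
    df = bysi_table.copy()
    if len(df) == 0:
        return SelectionResult(
            table=df.assign(selected=pd.Series(dtype=bool),
                            quadrant=pd.Series(dtype=object)),
            si_min=si_min, pi_max=pi_max, n_selected=0, n_total=0,
        )
    missing = df.index[df[["BYSI_SI", "BYSI_PI"]].isna().any(axis=1)].tolist()
    df = df.drop(index=missing)
    good_si = df["BYSI_SI"] > si_min
    good_pi = df["BYSI_PI"] < pi_max
    quadrant = np.where(
        good_pi & good_si, "III",
        np.where(good_pi & ~good_si, "II",
                 np.where(~good_pi & good_si, "IV", "I")),
    )
    df["quadrant"] = quadrant
    df["selected"] = (good_si & good_pi).to_numpy()
    return SelectionResult(
        table=df,
        si_min=si_min,
        pi_max=pi_max,
        n_selected=int(df["selected"].sum()),
        n_total=len(df),
        excluded=missing,
    )


def si_pi_table(trial) -> pd.DataFrame:
    """Accession x season means of SI and PI from a trial, in the long
    format :func:`fit_bivariate` expects."""
    si = trial.accession_season_means("SI").stack().rename("SI")
    pi = trial.accession_season_means("PI").stack().rename("PI")
    out = pd.concat([si, pi], axis=1).dropna().reset_index()
    return out.rename(columns={"level_0": "accession", "level_1": "season"})
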