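"""Quantitative-genetic parameter estimation for clonal germplasm trials.

The machinery follows conventional plant-breeding practice for randomized
clonal trials: a genotype x replication mean-squares decomposition gives the
genotypic variance by the expected-mean-squares identity
``GV = (MSG - MSE) / r`` (r = effective replication), and from GV and
PV = GV + EV the derived parameters are

* ``GCV = 100 * sqrt(GV) / mean`` and ``PCV = 100 * sqrt(PV) / mean``
  (genotypic / phenotypic coefficients of variation, %),
* broad-sense heritability ``H2 = 100 * GV / PV`` (%),
* genetic advance ``GA = k * sqrt(PV) * GV / PV`` for selection differential
  ``k`` (2.06 at 5% selection intensity), and ``GAM = 100 * GA / mean``.

Repeatability across seasons is the intraclass correlation of accession
season-means, an upper bound on broad-sense heritability in clonal material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import TrialTable

#: selection differential at 5% selection intensity
DEFAULT_K = 2.06


# -- seed and pod indices --------------------------------------------------


def seed_index(dry_seed_masses) -> float:
    """Seed index (g): mean dry mass of a single seed."""
    masses = np.asarray(dry_seed_masses, dtype=float)
    if masses.size == 0:
        raise ValueError("seed_index needs at least one seed mass")
    if np.any(masses <= 0):
        raise ValueError("seed masses must be positive")
    return float(masses.mean())


def pod_index(mean_seed_number: float, mean_dry_seed_mass: float) -> float:
    """Pod index: pods needed for 1 kg of dry seed (lower is better)."""
    if mean_seed_number <= 0 or mean_dry_seed_mass <= 0:
        raise ValueError("pod_index arguments must be positive")
    return 1000.0 / (mean_seed_number * mean_dry_seed_mass)


# -- variance components ---------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    MSG: float
    MSE: float
    r_eff: float
    grand_mean: float

    @property
    def GV(self) -> float:
        return max((self.MSG - self.MSE) / self.r_eff, 0.0)

    @property
    def EV(self) -> float:
        return self.MSE

    @property
    def PV(self) -> float:
        return self.GV + self.EV


def variance_components(trial: TrialTable, descriptor: str) -> VarianceComponents:
    """Genotype x replication mean squares for one descriptor.

    The two pooled seasons enter the replication stratum: each
    (season, graft) combination is one replication.  Unbalanced data are
    handled by sequential sums of squares (replication fitted before
    genotype) and a harmonic-mean effective replication ``r_eff``.
    """
    sub = trial.values(descriptor)
    y = sub["value"].to_numpy(dtype=float)
    geno = sub["accession"].to_numpy()
    rep = (sub["season"].astype(str) + ":" + sub["replicate"].astype(str)).to_numpy()

    glev, gidx = np.unique(geno, return_inverse=True)
    rlev, ridx = np.unique(rep, return_inverse=True)
    a, b, N = len(glev), len(rlev), len(y)
    if a < 2:
        raise ValueError("need >= 2 accessions")
    counts = np.bincount(gidx)
    if counts.min() < 2 or b < 2:
        raise ValueError("no residual df: each accession needs >= 2 replications")

    grand = y.mean()
    cells = np.bincount(gidx * b + ridx, minlength=a * b).reshape(a, b)
    balanced = np.all(cells == 1)
    if balanced:
        gmeans = np.bincount(gidx, weights=y) / counts
        rmeans = np.bincount(ridx, weights=y) / np.bincount(ridx)
        ss_total = ((y - grand) ** 2).sum()
        ss_g = b * ((gmeans - grand) ** 2).sum()
        ss_r = a * ((rmeans - grand) ** 2).sum()
        sse = ss_total - ss_g - ss_r
        df_e = (a - 1) * (b - 1)
        msg = ss_g / (a - 1)
    else:
        X_rep = np.zeros((N, b))
        X_rep[np.arange(N), ridx] = 1.0
        X_gen = np.zeros((N, a - 1))
        mask = gidx < a - 1
        X_gen[np.arange(N)[mask], gidx[mask]] = 1.0
        sse1 = _ols_sse(X_rep, y)
        sse2 = _ols_sse(np.hstack([X_rep, X_gen]), y)
        msg = (sse1 - sse2) / (a - 1)
        df_e = N - a - b + 1
        if df_e < 1:
            raise ValueError("no residual df")
        sse = sse2
    mse = sse / df_e
    r_eff = len(counts) / np.sum(1.0 / counts)  # harmonic mean replication
    return VarianceComponents(
        MSG=float(msg), MSE=float(mse), r_eff=float(r_eff), grand_mean=float(grand)
    )


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


# -- genetic parameters ----------------------------------------------------


def _band(value: float, low: float, high: float) -> str:
    if value < low:
        return "low"
    if value <= high:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class GeneticParams:
    """Genetic-parameter row for one descriptor (percent scales for GCV,
    PCV, H2 and GAM; GA in trait units)."""

    mean: float
    GV: float
    EV: float
    PV: float
    GCV: float
    PCV: float
    H2: float
    GA: float
    GAM: float
    k: float
    GCV_band: str = ""
    PCV_band: str = ""
    H2_band: str = ""
    GAM_band: str = ""


def genetic_parameters(
    GV: float, EV: float, mean: float, k: float = DEFAULT_K
) -> GeneticParams:
    """Derive GCV/PCV/H2/GA/GAM from variance components and the trait mean.

    Band thresholds follow the conventional classification: GCV/PCV and GAM
    low <10, moderate 10-20, high >20; H2 low <30, moderate 30-60, high >60.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if GV < 0 or EV < 0:
        raise ValueError("variances must be non-negative")
    PV = GV + EV
    if PV == 0:
        raise ValueError("PV must be positive")
    GCV = 100.0 * np.sqrt(GV) / mean
    PCV = 100.0 * np.sqrt(PV) / mean
    H2 = 100.0 * GV / PV
    GA = k * np.sqrt(PV) * (GV / PV)
    GAM = 100.0 * GA / mean
    return GeneticParams(
        mean=mean,
        GV=GV,
        EV=EV,
        PV=PV,
        GCV=float(GCV),
        PCV=float(PCV),
        H2=float(H2),
        GA=float(GA),
        GAM=float(GAM),
        k=k,
        GCV_band=_band(GCV, 10, 20),
        PCV_band=_band(PCV, 10, 20),
        H2_band=_band(H2, 30, 60),
        GAM_band=_band(GAM, 10, 20),
    )


def genetic_parameter_table(trial: TrialTable, k: float = DEFAULT_K) -> pd.DataFrame:
    """Variance components and genetic parameters for every quantitative
    descriptor present in the trial."""
    rows = {}
    present = set(trial.data["descriptor"])
    for t in trial.catalog.quantitative():
        if t.acronym not in present:
            continue
        vc = variance_components(trial, t.acronym)
        gp = genetic_parameters(vc.GV, vc.EV, vc.grand_mean, k=k)
        rows[t.acronym] = {
            "mean": gp.mean,
            "GV": gp.GV,
            "PV": gp.PV,
            "GCV_pct": gp.GCV,
            "PCV_pct": gp.PCV,
            "H2_pct": gp.H2,
            "GA": gp.GA,
            "GAM_pct": gp.GAM,
            "GCV_band": gp.GCV_band,
            "PCV_band": gp.PCV_band,
            "H2_band": gp.H2_band,
            "GAM_band": gp.GAM_band,
            "r_eff": vc.r_eff,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "descriptor"
    return df


# -- repeatability ---------------------------------------------------------


@dataclass(frozen=True)
class RepeatabilityEstimate:
    r_hat: float
    MSB: float
    MSW: float
    m_eff: float
    label: str

    @property
    def r_reported(self) -> float:
        """Truncated-at-zero value for reporting (raw value kept in r_hat)."""
        return max(self.r_hat, 0.0)


def repeatability(trial: TrialTable, descriptor: str) -> RepeatabilityEstimate:
    """Intraclass correlation of accession season-means across seasons.

    One-way ANOVA over accessions with seasons as repeated measures:
    ``r_hat = (MSB - MSW) / (MSB + (m - 1) * MSW)`` with m the (harmonic
    mean) number of seasons per accession.  ``r_hat > 0.40`` is labelled
    moderate-to-high.
    """
    mat = trial.accession_season_means(descriptor)
    m_per = mat.notna().sum(axis=1)
    keep = m_per >= 2
    if mat.shape[1] < 2 or keep.sum() < 2:
        raise ValueError("repeatability needs >= 2 seasons per accession")
    mat = mat[keep]
    m_per = m_per[keep].to_numpy(dtype=float)
    vals = mat.to_numpy(dtype=float)
    n = len(mat)
    N = int(m_per.sum())
    acc_means = np.nanmean(vals, axis=1)
    grand = np.nansum(vals) / N
    ssb = float(np.sum(m_per * (acc_means - grand) ** 2))
    ssw = float(np.nansum((vals - acc_means[:, None]) ** 2))
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    m_eff = n / np.sum(1.0 / m_per)
    r_hat = (msb - msw) / (msb + (m_eff - 1) * msw)
    label = "moderate-to-high" if r_hat > 0.40 else "low"
    return RepeatabilityEstimate(
        r_hat=float(r_hat), MSB=msb, MSW=msw, m_eff=float(m_eff), label=label
    )
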