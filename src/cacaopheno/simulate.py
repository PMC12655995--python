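"""Synthetic germplasm trials and phytochemical panels.

The generator emulates the statistical structure a clonal germplasm
characterization assumes: each accession carries a stable genotypic value per
trait, accessions fall into planted phenotypic clusters, genotypic values are
cross-correlated between traits, and every observation adds independent
environmental noise.  For quantitative trait ``t`` of accession ``i`` in
replicate ``j`` and season ``s``::

    y_tijs = mu_t + c_{k(i),t} + g_{i,t} + e_{tijs}

with cluster centroids ``c`` drawn once per cluster, accession deviations
``g`` jointly Gaussian with a configurable genotypic correlation matrix, and
residuals ``e ~ N(0, EV_t)``.  The centroid and deviation variances sum to
the configured genotypic variance ``GV_t``; the ``separation`` knob moves
variance between the two layers (large separation => well separated
clusters).  Qualitative descriptors are drawn per accession from
cluster-specific level frequencies.

Everything is driven by a single :class:`numpy.random.Generator` seed; the
same config yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import TraitCatalog, default_catalog
from .defaults import DEFAULT_TRAIT_CORRELATIONS, TRAIT_PARAMS
from .tables import PhytochemPanel, TrialTable


@dataclass
class SimConfig:
    """Configuration of a synthetic germplasm trial.

    Parameters
    ----------
    n_accessions : int
        Number of accessions (genotypes).
    n_reps : int
        Measured grafts per accession per season; >=2 so variance
        components are estimable.
    seasons : list of int
        Season labels (calendar years).
    K_true : int
        Planted number of phenotypic clusters.
    traits : dict
        ``acronym -> (mu, GV, EV)``.  Defaults to the full 33-descriptor set
        with published-scale means and variance components.
    separation : float
        Cluster separation multiplier: the between-cluster share of GV is
        ``separation**2 / (1 + separation**2)``, so the centroid spread is
        ``separation`` times the within-cluster genotypic spread.
    correlations : dict
        ``(acr_a, acr_b) -> r`` genotypic correlations; unlisted pairs are 0.
    qual_traits : list of str or None
        Qualitative descriptors to simulate (default: all 18).
    season_effects : dict
        Optional additive shift per season (same for all traits, in units of
        each trait's genotypic SD); default all zero (pooled-season model).
    seed : int
        RNG seed.
    """

    n_accessions: int = 113
    n_reps: int = 6
    seasons: tuple[int, ...] = (2023, 2024)
    K_true: int = 8
    traits: Optional[dict[str, tuple[float, float, float]]] = None
    separation: float = 1.5
    correlations: Optional[dict[tuple[str, str], float]] = None
    qual_traits: Optional[list[str]] = None
    season_effects: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def resolved_traits(self) -> dict[str, tuple[float, float, float]]:
        if self.traits is not None:
            return dict(self.traits)
        # a few descriptors have PV == GV at reported precision (H2 = 100%);
        # floor EV at 0.1% of GV so replicate noise stays strictly positive
        return {
            acr: (mu, gv, max(pv - gv, 1e-3 * gv))
            for acr, (mu, gv, pv) in TRAIT_PARAMS.items()
        }

    def validate(self) -> None:
        if self.n_accessions < 1:
            raise ValueError("n_accessions must be >= 1")
        if self.n_reps < 2:
            raise ValueError(
                "n_reps must be >= 2: variance decomposition needs replication"
            )
        if self.K_true > self.n_accessions:
            raise ValueError("K_true cannot exceed n_accessions")
        if len(self.seasons) < 1:
            raise ValueError("at least one season required")
        for acr, (mu, gv, ev) in self.resolved_traits().items():
            if gv < 0:
                raise ValueError(f"{acr}: GV must be >= 0")
            if ev <= 0:
                raise ValueError(f"{acr}: EV must be > 0")


def _correlation_matrix(
    trait_names: list[str], pairs: dict[tuple[str, str], float]
) -> np.ndarray:
    T = len(trait_names)
    idx = {t: i for i, t in enumerate(trait_names)}
    R = np.eye(T)
    for (a, b), r in pairs.items():
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


def _psd_sqrt(R: np.ndarray, *, tol: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    if w.min() < -tol:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def generate_trial(
    config: SimConfig, catalog: Optional[TraitCatalog] = None
) -> tuple[TrialTable, dict]:
    """Simulate a germplasm trial.

    Returns the :class:`TrialTable` and a truth record containing the planted
    cluster labels, per-accession genotypic values, the variance split, and
    the qualitative level frequencies per cluster.
    """
    config.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)

    traits = config.resolved_traits()
    names = list(traits)
    n, K = config.n_accessions, config.K_true
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]

    # balanced-ish random cluster assignment
    base = np.repeat(np.arange(K), int(np.ceil(n / K)))[:n]
    labels = rng.permutation(base)

    s2 = config.separation**2
    between_share = s2 / (1.0 + s2)

    mu = np.array([traits[t][0] for t in names])
    gv = np.array([traits[t][1] for t in names])
    ev = np.array([traits[t][2] for t in names])
    sd_cent = np.sqrt(gv * between_share)
    sd_dev = np.sqrt(gv * (1.0 - between_share))

    pairs = (
        config.correlations
        if config.correlations is not None
        else DEFAULT_TRAIT_CORRELATIONS
    )
    C = _psd_sqrt(_correlation_matrix(names, pairs))

    # Draw centroids, then standardize them (size-weighted) so the realized
    # between-cluster variance over accessions equals its target exactly;
    # otherwise only K values would be drawn and the planted GV would not be
    # recoverable even in large trials.
    centroids = rng.standard_normal((K, len(names)))  # K x T
    if K > 1:
        sizes = np.bincount(labels, minlength=K).astype(float)
        w = sizes / sizes.sum()
        cmean = w @ centroids
        centroids = centroids - cmean
        realized_sd = np.sqrt(w @ centroids**2)
        realized_sd[realized_sd == 0] = 1.0
        centroids = centroids / realized_sd * sd_cent
    else:
        centroids = np.zeros((1, len(names)))
        sd_dev = np.sqrt(gv)  # all genotypic variance in the deviations
    g_dev = (rng.standard_normal((n, len(names))) @ C) * sd_dev  # n x T
    genotypic = centroids[labels] + g_dev  # n x T

    n_reps, seasons = config.n_reps, list(config.seasons)
    m = n_reps * len(seasons)
    resid = rng.standard_normal((n, m, len(names))) * np.sqrt(ev)

    season_shift = np.array(
        [config.season_effects.get(s, 0.0) for s in seasons]
    )  # in genotypic-SD units per trait
    gsd = np.sqrt(np.maximum(gv, np.finfo(float).tiny))

    rep_ids = [f"R{j + 1}" for j in range(n_reps)]
    obs = mu + genotypic[:, None, :] + resid  # n x m x T
    col_rep, col_sea = [], []
    for s in seasons:
        for j in range(n_reps):
            col_rep.append(rep_ids[j])
            col_sea.append(s)
    frames = []
    acc_col = np.repeat(accessions, m)
    rep_col = np.tile(col_rep, n)
    sea_col = np.tile(col_sea, n)
    shift = season_shift[[seasons.index(s) for s in col_sea]]  # m
    data = obs + (shift[None, :, None] * gsd[None, None, :])
    for ti, t in enumerate(names):
        frames.append(
            pd.DataFrame(
                {
                    "accession": acc_col,
                    "replicate": rep_col,
                    "season": sea_col,
                    "descriptor": t,
                    "value": data[:, :, ti].reshape(-1),
                }
            )
        )

    # qualitative descriptors: accession-level attributes, constant across reps
    qual_names = (
        config.qual_traits
        if config.qual_traits is not None
        else [t.acronym for t in catalog.qualitative()]
    )
    qual_freqs: dict[str, np.ndarray] = {}
    for acr in qual_names:
        levels = catalog[acr].levels
        # cluster-specific level frequencies, Dirichlet-drawn once
        freqs = rng.dirichlet(np.ones(len(levels)), size=K)
        qual_freqs[acr] = freqs
        level_idx = np.array(
            [rng.choice(len(levels), p=freqs[labels[i]]) for i in range(n)]
        )
        frames.append(
            pd.DataFrame(
                {
                    "accession": acc_col,
                    "replicate": rep_col,
                    "season": sea_col,
                    "descriptor": acr,
                    "value": np.repeat(
                        [levels[k] for k in level_idx], m
                    ),
                }
            )
        )

    table = TrialTable(pd.concat(frames, ignore_index=True), catalog=catalog)
    truth = {
        "labels": pd.Series(labels, index=accessions, name="cluster"),
        "genotypic": pd.DataFrame(genotypic, index=accessions, columns=names),
        "mu": pd.Series(mu, index=names),
        "GV": pd.Series(gv, index=names),
        "EV": pd.Series(ev, index=names),
        "between_share": between_share,
        "qual_freqs": qual_freqs,
    }
    return table, truth


# -- phytochemical panel ---------------------------------------------------

# assay -> (between-accession mean, between-accession SD)
PANEL_DEFAULTS: dict[str, tuple[float, float]] = {
    "theobromine": (15.0, 5.0),
    "caffeine": (3.0, 1.2),
    "caffeic_acid": (1.0, 0.4),
    "catechin": (1.5, 1.0),
    "epicatechin": (10.0, 6.0),
    "cyanidin3G": (0.8, 0.3),
    "DPPH": (25.0, 6.0),
    "TPC": (50.0, 12.0),
    "L": (45.0, 5.0),
    "a": (8.0, 2.0),
    "b": (15.0, 4.0),
    "pH": (5.6, 0.3),
    "TA": (1.2, 0.3),
}

# between-accession correlations typical of cacao cotyledon panels
PANEL_CORRELATIONS: dict[tuple[str, str], float] = {
    ("theobromine", "TPC"): 0.95,
    ("TPC", "b"): -0.92,
    ("theobromine", "b"): -0.87,
    ("cyanidin3G", "caffeine"): 0.86,
    ("caffeic_acid", "caffeine"): -0.83,
    ("caffeic_acid", "cyanidin3G"): -0.71,
}


def generate_phytochem(
    n_accessions: int,
    seed: int = 0,
    n_reps: int = 3,
    noise_scale: float = 0.03,
    catechin_absent_prob: float = 7.0 / 15.0,
    correlations: Optional[dict[tuple[str, str], float]] = None,
) -> PhytochemPanel:
    """Simulate a phytochemical assay panel (triplicate assays by default).

    ``noise_scale`` is the within-triplicate SD as a fraction of the assay
    mean (0 gives identical triplicates).  A random subset of accessions has
    no detectable catechin, mirroring real cotyledon panels.
    """
    if n_accessions < 1:
        raise ValueError("n_accessions must be >= 1")
    rng = np.random.default_rng(seed)
    assays = list(PANEL_DEFAULTS)
    pairs = correlations if correlations is not None else PANEL_CORRELATIONS
    C = _psd_sqrt(_correlation_matrix(assays, pairs))

    mu = np.array([PANEL_DEFAULTS[a][0] for a in assays])
    sd = np.array([PANEL_DEFAULTS[a][1] for a in assays])
    acc_values = mu + (rng.standard_normal((n_accessions, len(assays))) @ C) * sd

    # keep values physical: concentrations >= 0, L* in [0, 100]
    nonneg = [a for a in assays if a not in ("a", "b")]
    for a in nonneg:
        i = assays.index(a)
        acc_values[:, i] = np.clip(acc_values[:, i], 0.0, None)
    acc_values[:, assays.index("L")] = np.clip(
        acc_values[:, assays.index("L")], 0.0, 100.0
    )

    absent = rng.random(n_accessions) < catechin_absent_prob

    accessions = [f"ACC{i + 1:04d}" for i in range(n_accessions)]
    rows = []
    for i, acc in enumerate(accessions):
        for r in range(n_reps):
            noise = rng.standard_normal(len(assays)) * (noise_scale * np.abs(mu))
            vals = acc_values[i] + noise
            for a in nonneg:
                j = assays.index(a)
                vals[j] = max(vals[j], 0.0)
            vals[assays.index("L")] = min(max(vals[assays.index("L")], 0.0), 100.0)
            rec = {"accession": acc, "replicate": r + 1}
            rec.update(dict(zip(assays, vals)))
            if absent[i]:
                rec["catechin"] = np.nan
            rows.append(rec)
    return PhytochemPanel(pd.DataFrame(rows))
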