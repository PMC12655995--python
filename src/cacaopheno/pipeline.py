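"""End-to-end orchestration of the characterization pipeline.

Stages run in dependency order: input (simulate or read files) ->
descriptive summaries -> genetic parameters -> multivariate clustering ->
per-cluster inference -> Bayesian bivariate selection -> phytochemical
network.  A single global seed expands into fixed per-stage offsets so
toggling one stage never shifts another stage's random stream.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import descriptive, groups, io, multivariate, phytochem, quantgen, selection
from .simulate import SimConfig, generate_phytochem, generate_trial
from .tables import PhytochemPanel, TrialTable

log = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "phytochem_sim": 1,
    "cluster": 2,
    "grouptest": 3,
    "select": 4,
    "au": 5,
}


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML/JSON serializable)."""

    mode: str = "simulate"  # "simulate" | "files"
    trial_path: Optional[str] = None
    panel_path: Optional[str] = None
    seed: int = 0
    stages: tuple[str, ...] = (
        "describe", "quantgen", "cluster", "grouptest", "select", "phytochem",
    )
    # stage parameters
    grubbs_alpha: float = 0.05
    k_selection_differential: float = quantgen.DEFAULT_K
    k_override: Optional[int] = None
    k_range: tuple[int, int] = (2, 12)
    gap_B: int = 50
    au_B: int = 200
    mcmc_iterations: int = 5000
    mcmc_burnin: int = 1000
    mcmc_thin: int = 2
    si_min: float = selection.DEFAULT_SI_MIN
    pi_max: float = selection.DEFAULT_PI_MAX
    network_r_min: float = 0.7
    network_alpha: float = 0.05
    alpha: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim_raw = raw.pop("sim", {})
        corr = sim_raw.get("correlations")
        if corr:
            sim_raw["correlations"] = {
                tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                for k, v in corr.items()
            }
        sim = SimConfig(**sim_raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw, sim=sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = asdict(self.sim)
        if sim.get("correlations"):
            sim["correlations"] = {
                f"{a}|{b}": r for (a, b), r in sim["correlations"].items()
            }
        d["sim"] = sim
        return d


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute the configured stages; returns a result bundle dict and
    writes CSV/Newick/JSON artifacts under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    bundle: dict = {"config": config.to_dict()}
    tables_out: dict[str, pd.DataFrame] = {}
    newick = None

    # -- input -------------------------------------------------------------
    if config.mode == "simulate":
        sim_cfg = config.sim
        sim_cfg.seed = config.stage_seed("simulate")
        trial, truth = generate_trial(sim_cfg)
        bundle["truth"] = truth
        panel = generate_phytochem(
            n_accessions=15, seed=config.stage_seed("phytochem_sim")
        )
    elif config.mode == "files":
        if not config.trial_path:
            raise ValueError("files mode requires trial_path")
        trial = io.read_trial(config.trial_path)
        truth = None
        panel = io.read_panel(config.panel_path) if config.panel_path else None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    bundle["trial"] = trial

    # -- describe ----------------------------------------------------------
    if "describe" in config.stages:
        summary = descriptive.summary_table(trial)
        clean_matrix, outlier_report = descriptive.screen_trial(
            trial, alpha=config.grubbs_alpha
        )
        bundle["summary"] = summary
        bundle["trait_matrix"] = clean_matrix
        bundle["outliers"] = outlier_report
        tables_out["descriptive_summary"] = summary
        tables_out["outlier_report"] = outlier_report
    else:
        bundle["trait_matrix"] = trial.trait_matrix()

    # -- quantgen ----------------------------------------------------------
    if "quantgen" in config.stages:
        gp = quantgen.genetic_parameter_table(
            trial, k=config.k_selection_differential
        )
        bundle["genetic_parameters"] = gp
        tables_out["genetic_parameters"] = gp.round(
            {c: 2 for c in gp.columns if gp[c].dtype.kind == "f"}
        )
        rep_rows = {}
        for d in ("SI", "PI"):
            if d in set(trial.data["descriptor"]) and len(trial.seasons) >= 2:
                r = quantgen.repeatability(trial, d)
                rep_rows[d] = {
                    "r_hat": r.r_hat, "MSB": r.MSB, "MSW": r.MSW,
                    "label": r.label,
                }
        if rep_rows:
            bundle["repeatability"] = pd.DataFrame(rep_rows).T

    # -- cluster -----------------------------------------------------------
    labels = None
    if "cluster" in config.stages:
        X = bundle["trait_matrix"]
        model = multivariate.WardClusterer(
            n_clusters=config.k_override,
            k_range=config.k_range,
            B_gap=config.gap_B,
            random_state=config.stage_seed("cluster"),
        ).fit(X)
        pca_model = multivariate.pca(X)
        corr = multivariate.pearson_matrix(X)
        labels = model.labels_series()
        bundle["cluster_model"] = model
        bundle["pca"] = pca_model
        bundle["correlations"] = corr
        bundle["cluster_labels"] = labels
        summary = model.distance_summary_
        dist_table = summary.matrix.round(2)
        dist_table["mean_distance"] = summary.mean_distance.round(2)
        tables_out["cluster_distances"] = dist_table
        tables_out["cluster_labels"] = labels.to_frame()
        tables_out["correlation_matrix"] = corr.r.round(3)
        newick = io.linkage_to_newick(
            model.linkage_, [str(a) for a in X.index]
        )
        if config.au_B:
            au = model.au_support(
                B=config.au_B, seed=config.stage_seed("au")
            )
            bundle["au_support"] = au
            tables_out["au_support"] = au.drop(columns="leaves")

    # -- grouptest ---------------------------------------------------------
    if "grouptest" in config.stages:
        if labels is None:
            raise ValueError("grouptest stage requires the cluster stage")
        table, results = groups.cluster_anova_table(
            trial, labels, alpha=config.alpha,
            seed=config.stage_seed("grouptest"),
        )
        bundle["cluster_means"] = table
        bundle["group_tests"] = results
        tables_out["cluster_means"] = table

    # -- select ------------------------------------------------------------
    if "select" in config.stages:
        for d in ("SI", "PI"):
            if d not in set(trial.data["descriptor"]):
                raise ValueError(
                    f"select stage requires descriptor {d} (quantgen indices)"
                )
        si_pi = selection.si_pi_table(trial)
        model = selection.fit_bivariate(
            si_pi,
            iterations=config.mcmc_iterations,
            burnin=config.mcmc_burnin,
            thin=config.mcmc_thin,
            seed=config.stage_seed("select"),
        )
        bysi_df = selection.bysi(model)
        result = selection.select_promising(
            bysi_df, si_min=config.si_min, pi_max=config.pi_max
        )
        bundle["selection_model"] = model
        bundle["selection"] = result
        tables_out["selection"] = result.table
        log.info(
            "selected %d/%d accessions (%.2f%%)",
            result.n_selected, result.n_total, result.selected_pct,
        )

    # -- phytochem ---------------------------------------------------------
    if "phytochem" in config.stages:
        if panel is None:
            log.info("phytochem stage skipped: no panel available")
        else:
            G = phytochem.build_network(
                panel, r_min=config.network_r_min, alpha=config.network_alpha
            )
            bundle["network"] = G
            tables_out["network_edges"] = phytochem.network_edge_list(G)
            means = panel.accession_means()
            tc = means.apply(
                lambda row: phytochem.tc_ratio_classify(
                    row["theobromine"], row["caffeine"]
                ),
                axis=1,
            )
            tc_df = pd.DataFrame(
                [(r, lbl) for r, lbl in tc], index=means.index,
                columns=["tc_ratio", "group"],
            )
            bundle["tc_classification"] = tc_df
            tables_out["tc_classification"] = tc_df

    written = io.write_outputs(tables_out, outdir, newick=newick)
    with open(os.path.join(outdir, "run_config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, default=str)
    bundle["files"] = written
    return bundle
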