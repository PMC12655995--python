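"""Phytochemical analysis: calibration inversion, theobromine/caffeine ratio
classification, and Pearson correlation networks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .multivariate import pearson_matrix
from .tables import PhytochemPanel


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration ``y = m*x + b`` mapping analyte concentration x to
    instrument response y."""

    slope: float
    intercept: float
    r_squared: float = np.nan
    response: str = ""
    units: str = ""

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not np.isnan(self.r_squared) and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must be in [0, 1]")

    def forward(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


# standard curves for antioxidant capacity (Trolox) and total phenolics
# (gallic acid)
TROLOX_CURVE = CalibrationCurve(0.2321, -1.2859, 0.9978, "DPPH", "mg TE/g")
GALLIC_CURVE = CalibrationCurve(0.0036, 0.1872, 0.9982, "TPC", "mg GAE/g")


def invert_calibration(curve: CalibrationCurve, response) -> np.ndarray:
    """Analyte concentration ``x = (y - b) / m`` from a measured response.

    Negative results are returned as-is (below calibration range), never
    silently clipped; callers decide how to flag them.
    """
    y = np.asarray(response, dtype=float)
    x = (y - curve.intercept) / curve.slope
    return x if x.ndim else float(x)


def below_range(curve: CalibrationCurve, response) -> np.ndarray:
    """Boolean mask of responses that invert to negative concentrations."""
    x = np.atleast_1d(invert_calibration(curve, response))
    return x < 0


TC_RATIO_BANDS = (
    ("Criollo", 2.0),     # ratio < 2
    ("Trinitario", 9.0),  # 2 <= ratio <= 9 (closed interval)
    ("Forastero", np.inf),
)


def tc_ratio_classify(theobromine: float, caffeine: float) -> tuple[float, str]:
    """Classify by the theobromine/caffeine ratio.

    Criollo-type < 2, Trinitario-type in the closed interval [2, 9],
    Forastero-type > 9.  Zero caffeine gives an undefined ratio and the
    label ``"unclassifiable"``.
    """
    if caffeine < 0 or theobromine < 0:
        raise ValueError("concentrations must be non-negative")
    if caffeine == 0:
        return np.nan, "unclassifiable"
    ratio = theobromine / caffeine
    if ratio < 2.0:
        return ratio, "Criollo"
    if ratio <= 9.0:
        return ratio, "Trinitario"
    return ratio, "Forastero"


def build_network(
    panel: PhytochemPanel,
    r_min: float = 0.7,
    alpha: float = 0.05,
    variables: Optional[list[str]] = None,
) -> nx.Graph:
    """Pearson correlation network on accession-level assay means.

    Triplicates are averaged per accession first; an edge (with attributes
    ``r`` and ``p``) is kept iff ``|r| >= r_min`` and ``p < alpha``.
    Constant variables are excluded and recorded in the graph attribute
    ``excluded``.
    """
    means = panel.accession_means()
    if variables is not None:
        means = means[variables]
    if len(means) < 4:
        raise ValueError("need >= 4 accessions with assay values")
    means = means.dropna(axis=1, how="all")
    res = pearson_matrix(means)
    G = nx.Graph()
    kept = [c for c in means.columns if c not in res.constant_columns]
    G.add_nodes_from(kept)
    G.graph["excluded"] = list(res.constant_columns)
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            r, p = res.r.loc[a, b], res.p.loc[a, b]
            if np.isnan(r):
                continue
            if abs(r) >= r_min and p < alpha:
                G.add_edge(a, b, r=float(r), p=float(p))
    return G


def network_edge_list(G: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": a, "target": b, "r": d["r"], "p": d["p"]}
        for a, b, d in G.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p"])
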