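"""Descriptive summaries, Grubbs outlier screening and qualitative frequencies."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .tables import TrialTable


@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-descriptor summary statistics; CV is 100*SD/mean (percent)."""

    descriptor: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    cv: float


def summarize(
    trial: TrialTable, descriptor: str, level: str = "accession-mean"
) -> DescriptiveSummary:
    """Summarize a quantitative descriptor.

    ``level`` is ``"observation"`` (raw values) or ``"accession-mean"``
    (per-accession means pooled over replicates and seasons — the level at
    which germplasm ranges are conventionally reported).
    """
    if not trial.catalog.is_quantitative(descriptor):
        raise TypeError(f"{descriptor} is qualitative; summarize needs a "
                        "quantitative descriptor")
    if level == "accession-mean":
        vals = trial.accession_means(descriptor).to_numpy(dtype=float)
    elif level == "observation":
        vals = trial.values(descriptor)["value"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown level {level!r}")
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError(f"{descriptor}: need >=2 values to summarize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return DescriptiveSummary(
        descriptor=descriptor,
        n=len(vals),
        mean=mean,
        sd=sd,
        minimum=float(np.min(vals)),
        maximum=float(np.max(vals)),
        cv=float(cv),
    )


def summary_table(trial: TrialTable, level: str = "accession-mean") -> pd.DataFrame:
    """Descriptive summary for every quantitative descriptor in the trial."""
    rows = []
    present = set(trial.data["descriptor"])
    for t in trial.catalog.quantitative():
        if t.acronym in present:
            s = summarize(trial, t.acronym, level=level)
            rows.append(
                {
                    "descriptor": s.descriptor,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "min": s.minimum,
                    "max": s.maximum,
                    "cv_pct": s.cv,
                }
            )
    return pd.DataFrame(rows).set_index("descriptor")


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for the max studentized deviation."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(values, alpha: float = 0.05) -> list[int]:
    """Iterative two-sided Grubbs outlier screen.

    At each pass the most extreme point (max ``|x - mean| / sd``) is tested
    against the t-based critical value; if rejected it is removed and the
    test repeats on the remainder, until no rejection or fewer than 3 points
    remain.  Returns the indices of removed points, in removal order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if len(values) < 3:
        raise ValueError("Grubbs test needs n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    active = list(range(len(values)))
    removed: list[int] = []
    while len(active) >= 3:
        x = values[active]
        sd = x.std(ddof=1)
        if sd == 0.0:
            break  # no outliers definable in constant data
        dev = np.abs(x - x.mean())
        j = int(np.argmax(dev))
        G = dev[j] / sd
        if G > grubbs_critical(len(x), alpha):
            if len(active) == 3:
                break  # the test needs n >= 3 to continue; cap at n - 3
            removed.append(active.pop(j))
        else:
            break
    return removed


def screen_trial(
    trial: TrialTable, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the Grubbs screen to each quantitative descriptor's accession
    means; returns (clean accession x descriptor matrix, removal report).

    Screening on accession means (rather than raw observations) removes
    accessions whose genotypic value for a descriptor is implausible, while
    replicate-level noise is handled by the variance decomposition.
    """
    mat = trial.trait_matrix()
    records = []
    for col in mat.columns:
        vals = mat[col].dropna()
        if len(vals) < 3:
            continue
        removed = grubbs_screen(vals.to_numpy(), alpha=alpha)
        for order, idx in enumerate(removed):
            acc = vals.index[idx]
            records.append(
                {
                    "descriptor": col,
                    "accession": acc,
                    "value": vals.iloc[idx],
                    "order": order,
                }
            )
            mat.loc[acc, col] = np.nan
    report = pd.DataFrame(records, columns=["descriptor", "accession", "value", "order"])
    return mat, report


def qual_frequencies(
    trial: TrialTable,
    descriptor: str,
    cluster_labels: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-level counts and percentages of a qualitative descriptor.

    Each accession contributes one record: its modal level across replicate
    observations (ties broken by catalog level order).  With
    ``cluster_labels`` (accession -> cluster id), frequencies are tabulated
    per cluster; otherwise overall.
    """
    trait = trial.catalog[descriptor]
    if trait.kind != "qualitative":
        raise TypeError(f"{descriptor} is not qualitative")
    sub = trial.values(descriptor)
    level_order = {lvl: i for i, lvl in enumerate(trait.levels)}

    def modal(series: pd.Series) -> str:
        counts = series.value_counts()
        top = counts[counts == counts.max()].index
        return min(top, key=lambda lvl: level_order[lvl])

    per_acc = sub.groupby("accession")["value"].apply(modal)

    if cluster_labels is not None:
        unknown = set(per_acc.index) - set(cluster_labels.index)
        if unknown:
            raise ValueError(f"no cluster label for accessions: {sorted(unknown)[:5]}")
        groups = per_acc.groupby(cluster_labels.reindex(per_acc.index))
    else:
        groups = [("overall", per_acc)]

    rows = []
    for gname, gvals in groups:
        counts = gvals.value_counts()
        total = counts.sum()
        for lvl in trait.levels:
            c = int(counts.get(lvl, 0))
            rows.append(
                {
                    "descriptor": descriptor,
                    "group": gname,
                    "level": lvl,
                    "count": c,
                    "percent": 100.0 * c / total,
                }
            )
    return pd.DataFrame(rows)
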