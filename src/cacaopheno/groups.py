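"""Per-cluster inference: assumption checks, unbalanced one-way ANOVA and
Tukey HSD compact letter displays.

The model is the fixed-effects one-way layout ``y_ij = mu + alpha_i + e_ij``
with each accession (its mean over replicates and seasons) treated as one
replicate of its phenotypic cluster.  Normality of residuals is tested with
a Lilliefors-corrected Kolmogorov-Smirnov test (parameters estimated from
the data, Monte-Carlo p-value), variance homogeneity with Bartlett's test,
and pairwise differences with the Tukey-Kramer studentized-range procedure
summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .tables import TrialTable


def _group_arrays(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    keys = pd.unique(labels)
    groups = [values[labels == k] for k in keys]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    return list(keys), groups


def lilliefors_ks(values, n_sims: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """KS normality test with mean and SD estimated from the data.

    The null distribution of the statistic is obtained by Monte-Carlo
    (standard-normal samples of the same size, re-estimating parameters each
    time), which corrects the anti-conservatism of the plain KS p-value.
    Returns (statistic, p).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for the normality check")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: normality undefined")
    d_obs = stats.kstest((x - x.mean()) / sd, "norm").statistic

    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sims, n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(
        axis=1, ddof=1, keepdims=True
    )
    sims.sort(axis=1)
    grid = np.arange(1, n + 1) / n
    cdf = stats.norm.cdf(sims)
    d_null = np.maximum(np.abs(grid - cdf), np.abs(grid - 1.0 / n - cdf)).max(axis=1)
    p = (np.sum(d_null >= d_obs) + 1.0) / (n_sims + 1.0)
    return float(d_obs), float(p)


@dataclass
class AssumptionChecks:
    ks_stat: float
    ks_p: float
    bartlett_stat: float
    bartlett_p: float
    flags: list[str] = field(default_factory=list)


def assumption_checks(
    values, labels, n_sims: int = 10_000, seed: int = 0
) -> AssumptionChecks:
    """Normality (Lilliefors KS on centered residuals) and homogeneity of
    variances (Bartlett) for a grouped sample."""
    keys, groups = _group_arrays(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    resid = np.concatenate([g - g.mean() for g in groups])
    ks_stat, ks_p = lilliefors_ks(resid, n_sims=n_sims, seed=seed)
    flags = []
    if any(g.std(ddof=1) == 0 for g in groups):
        bart_stat, bart_p = np.nan, np.nan
        flags.append("bartlett-undefined-zero-variance-group")
    else:
        bart_stat, bart_p = stats.bartlett(*groups)
    return AssumptionChecks(
        ks_stat=ks_stat,
        ks_p=ks_p,
        bartlett_stat=float(bart_stat),
        bartlett_p=float(bart_p),
        flags=flags,
    )


def oneway_anova(values, labels) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA (unbalanced); returns (F, p)."""
    keys, groups = _group_arrays(values, labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    N = sum(len(g) for g in groups)
    if N <= len(groups):
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, N - len(groups)
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (np.inf, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


# -- Tukey-Kramer + compact letter display ---------------------------------


def tukey_pairwise(values, labels) -> pd.DataFrame:
    """Tukey-Kramer adjusted p-values for all group pairs.

    Uses the studentized-range distribution with the unbalanced-size
    correction ``se_ij = sqrt(MSE/2 * (1/n_i + 1/n_j))``.
    """
    keys, groups = _group_arrays(values, labels)
    k = len(keys)
    N = sum(len(g) for g in groups)
    df_e = N - k
    if df_e < 1:
        raise ValueError("no residual degrees of freedom")
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_e
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                p = 1.0 if means[i] == means[j] else 0.0
                q = np.inf if p == 0.0 else 0.0
            else:
                q = abs(means[i] - means[j]) / se
                p = float(stats.studentized_range.sf(q, k, df_e))
            rows.append(
                {"group1": keys[i], "group2": keys[j], "meandiff":
                 float(means[i] - means[j]), "q": float(q), "p_adj": p}
            )
    return pd.DataFrame(rows)


def _insert_absorb(order: list, sig_pairs: set[frozenset]) -> dict:
    """Compact letter display by insert-and-absorb.

    ``order`` lists groups by descending mean; ``sig_pairs`` holds the
    significantly different pairs.  Letters are assigned so that two groups
    share a letter iff they are *not* significantly different, with 'a'
    given to the largest mean.
    """
    # letters represented as sets of groups; start with one letter holding all
    letters: list[set] = [set(order)]
    for pair in sorted(sig_pairs, key=lambda s: sorted(map(str, s))):
        g1, g2 = tuple(pair)
        split: list[set] = []
        for s in letters:
            if g1 in s and g2 in s:
                # split this letter into two, each dropping one of the pair
                split.append(s - {g1})
                split.append(s - {g2})
            else:
                split.append(s)
        letters = split
        # absorb letters that are subsets of another
        letters = [
            s
            for i, s in enumerate(letters)
            if not any(i != j and s < t for j, t in enumerate(letters))
        ]
        # deduplicate while preserving order
        seen, uniq = [], []
        for s in letters:
            if s not in seen:
                seen.append(s)
                uniq.append(s)
        letters = uniq
    # order letters by the best (highest-mean) group they contain
    rank = {g: i for i, g in enumerate(order)}
    letters.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict = {g: "" for g in order}
    for li, s in enumerate(letters):
        for g in order:
            if g in s:
                assignment[g] += alphabet[li % len(alphabet)]
    return assignment


def _prune_redundant(assignment: dict, order: list, sig_pairs: set) -> dict:
    """Drop letters whose removal keeps sharing <=> non-significance intact
    (and every group covered), yielding a minimal display."""

    def consistent(asg):
        for i, g in enumerate(order):
            if not asg[g]:
                return False
            for h in order[i + 1:]:
                share = bool(set(asg[g]) & set(asg[h]))
                if share == (frozenset((g, h)) in sig_pairs):
                    return False
        return True

    asg = {g: s for g, s in assignment.items()}
    changed = True
    while changed:
        changed = False
        for g in order:
            for ch in asg[g]:
                trial = dict(asg)
                trial[g] = asg[g].replace(ch, "")
                if consistent(trial):
                    asg = trial
                    changed = True
                    break
    # drop letters that vanished everywhere, re-densifying the alphabet
    used = sorted({c for s in asg.values() for c in s})
    remap = {c: "abcdefghijklmnopqrstuvwxyz"[i] for i, c in enumerate(used)}
    return {g: "".join(remap[c] for c in s) for g, s in asg.items()}


def tukey_letters(values, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Compact letter display of Tukey-Kramer comparisons.

    Groups are ordered by descending mean; two groups share a letter iff
    their adjusted p >= alpha.  Returns a DataFrame with group, n, mean, sd
    and letters.
    """
    keys, groups = _group_arrays(values, labels)
    pw = tukey_pairwise(values, labels)
    sig = {
        frozenset((r.group1, r.group2))
        for r in pw.itertuples()
        if r.p_adj < alpha
    }
    means = {k: g.mean() for k, g in zip(keys, groups)}
    order = sorted(keys, key=lambda k: -means[k])
    assignment = _insert_absorb(order, sig)
    assignment = _prune_redundant(assignment, order, sig)
    rows = [
        {
            "group": k,
            "n": len(groups[keys.index(k)]),
            "mean": float(means[k]),
            "sd": float(groups[keys.index(k)].std(ddof=1)),
            "letters": assignment[k],
        }
        for k in order
    ]
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    descriptor: str
    ks_p: float
    bartlett_p: float
    F: float
    p: float
    letters: pd.DataFrame
    alpha: float
    flags: list[str] = field(default_factory=list)


def cluster_anova_table(
    trial: TrialTable,
    cluster_labels: pd.Series,
    descriptors: Optional[list[str]] = None,
    alpha: float = 0.05,
    ks_sims: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, GroupTestResult]]:
    """Per-descriptor cluster comparison table (means +- SD with letters).

    Accession means over replicates/seasons are the replicates within each
    phenotypic cluster.  No multiplicity correction is applied across
    descriptors (each descriptor is reported marginally); this is recorded
    in the result metadata.
    """
    if descriptors is None:
        descriptors = [
            t.acronym
            for t in trial.catalog.quantitative()
            if t.acronym in set(trial.data["descriptor"])
        ]
    results: dict[str, GroupTestResult] = {}
    display_rows = {}
    for d in descriptors:
        means = trial.accession_means(d)
        labels = cluster_labels.reindex(means.index)
        if labels.isna().any():
            raise ValueError(f"missing cluster labels for some accessions ({d})")
        checks = assumption_checks(
            means.to_numpy(), labels.to_numpy(), n_sims=ks_sims, seed=seed
        )
        F, p = oneway_anova(means.to_numpy(), labels.to_numpy())
        letters = tukey_letters(means.to_numpy(), labels.to_numpy(), alpha=alpha)
        results[d] = GroupTestResult(
            descriptor=d,
            ks_p=checks.ks_p,
            bartlett_p=checks.bartlett_p,
            F=F,
            p=p,
            letters=letters,
            alpha=alpha,
            flags=checks.flags + ["no-across-descriptor-correction"],
        )
        display_rows[d] = {
            f"C{int(r.group)}": f"{r.mean:.2f} ± {r.sd:.2f} {r.letters}"
            for r in letters.itertuples()
        }
    table = pd.DataFrame.from_dict(display_rows, orient="index")
    table = table.reindex(sorted(table.columns, key=lambda c: int(c[1:])), axis=1)
    table.index.name = "descriptor"
    return table, results
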