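"""In-memory containers for germplasm trial data.

The trial is kept in long (tidy) format — one row per
(accession, replicate, season, descriptor) observation — which tolerates the
unbalanced designs typical of perennial germplasm banks where not every graft
yields every descriptor in every season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import TraitCatalog, default_catalog

TRIAL_COLUMNS = ["accession", "replicate", "season", "descriptor", "value"]
KEY_COLUMNS = ["accession", "replicate", "season", "descriptor"]


class ValidationError(ValueError):
    """Raised when a table violates the catalog or key-uniqueness contract."""


@dataclass
class TrialTable:
    """Long-format germplasm trial observations.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``accession, replicate, season, descriptor, value``.
        Quantitative values are floats, qualitative values level strings.
    catalog : TraitCatalog
        Descriptor definitions the table is validated against.
    passport : dict, optional
        Per-accession passport metadata (province, district, coordinates...).
    """

    data: pd.DataFrame
    catalog: TraitCatalog = field(default_factory=default_catalog)
    passport: Optional[dict] = None

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("trial table is empty")
        unknown = sorted(set(df["descriptor"]) - set(self.catalog.acronyms))
        if unknown:
            raise ValidationError(f"unknown descriptors: {unknown}")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            bad = df.loc[dup, KEY_COLUMNS].head(5).to_dict("records")
            raise ValidationError(f"duplicate observation keys, e.g. {bad}")
        for trait in self.catalog.qualitative():
            vals = df.loc[df["descriptor"] == trait.acronym, "value"]
            bad_levels = sorted(set(vals.astype(str)) - set(trait.levels))
            if len(vals) and bad_levels:
                raise ValidationError(
                    f"illegal levels for {trait.acronym}: {bad_levels}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def accessions(self) -> list:
        return sorted(self.data["accession"].unique())

    @property
    def seasons(self) -> list:
        return sorted(self.data["season"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def quantitative(self) -> pd.DataFrame:
        quant = {t.acronym for t in self.catalog.quantitative()}
        sub = self.data[self.data["descriptor"].isin(quant)].copy()
        sub["value"] = sub["value"].astype(float)
        return sub

    def qualitative(self) -> pd.DataFrame:
        qual = {t.acronym for t in self.catalog.qualitative()}
        return self.data[self.data["descriptor"].isin(qual)].copy()

    def values(self, descriptor: str) -> pd.DataFrame:
        """All observations of one descriptor (long sub-table)."""
        if descriptor not in self.catalog:
            raise KeyError(f"descriptor {descriptor!r} not in catalog")
        return self.data[self.data["descriptor"] == descriptor].copy()

    def accession_means(self, descriptor: str) -> pd.Series:
        """Per-accession mean of a quantitative descriptor over all
        replicates and seasons."""
        if not self.catalog.is_quantitative(descriptor):
            raise TypeError(f"{descriptor} is not quantitative")
        sub = self.values(descriptor)
        return sub.groupby("accession")["value"].mean().astype(float)

    def accession_season_means(self, descriptor: str) -> pd.DataFrame:
        """Accession x season matrix of means for a quantitative descriptor."""
        if not self.catalog.is_quantitative(descriptor):
            raise TypeError(f"{descriptor} is not quantitative")
        sub = self.values(descriptor)
        sub["value"] = sub["value"].astype(float)
        return sub.pivot_table(
            index="accession", columns="season", values="value", aggfunc="mean"
        )

    def trait_matrix(self, descriptors: Optional[list[str]] = None) -> pd.DataFrame:
        """Accession x descriptor matrix of accession means (quantitative).

        Cells with no observation are left as NaN; downstream multivariate
        steps mean-impute them.
        """
        if descriptors is None:
            descriptors = [t.acronym for t in self.catalog.quantitative()]
        sub = self.quantitative()
        sub = sub[sub["descriptor"].isin(descriptors)]
        mat = sub.pivot_table(
            index="accession", columns="descriptor", values="value", aggfunc="mean"
        )
        return mat.reindex(columns=[d for d in descriptors if d in mat.columns])


PANEL_ASSAYS = [
    "theobromine",
    "caffeine",
    "caffeic_acid",
    "catechin",
    "epicatechin",
    "cyanidin3G",
    "DPPH",
    "TPC",
    "L",
    "a",
    "b",
    "pH",
    "TA",
]


@dataclass
class PhytochemPanel:
    """Phytochemical assay panel: one row per accession x replicate.

    Columns: ``accession``, ``replicate`` plus any of the standard assays
    (methylxanthines and phenolics in mg/g, DPPH in mg TE/g, TPC in mg GAE/g,
    CIELAB L*/a*/b*, pH, titratable acidity in % acetic acid).  Absent
    compounds (e.g. catechin in some accessions) are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for c in ("accession", "replicate"):
            if c not in df.columns:
                raise ValidationError(f"panel missing column {c!r}")
        assay_cols = self.assay_columns
        if not assay_cols:
            raise ValidationError("panel has no assay columns")
        conc = [c for c in assay_cols if c not in ("L", "a", "b", "pH")]
        vals = df[conc].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative concentrations in panel")
        if "L" in df.columns:
            L = df["L"].to_numpy(dtype=float)
            if np.nanmin(L, initial=0) < 0 or np.nanmax(L, initial=0) > 100:
                raise ValidationError("CIELAB L* outside [0, 100]")

    @property
    def assay_columns(self) -> list[str]:
        return [c for c in PANEL_ASSAYS if c in self.data.columns]

    def accession_means(self) -> pd.DataFrame:
        """Mean over assay replicates (typically triplicates), per accession."""
        return self.data.groupby("accession")[self.assay_columns].mean()
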