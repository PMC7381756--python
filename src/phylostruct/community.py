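"""Site-by-species incidence data: reading, subplot unions, species pool."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phylostruct.trees import canonical_label

logger = logging.getLogger(__name__)

HABITAT_COLUMN = "habitat"


class CommunityError(ValueError):
    """Invalid community matrix input."""


@dataclass
class CommunityMatrix:
    """Sites × species incidence (0/1) with optional per-site habitat labels.

    Invariants enforced on construction: entries are 0/1, every site holds
    at least one species, and species observed at no site are removed.
    """

    incidence: pd.DataFrame
    habitat: pd.Series | None = None

    def __post_init__(self) -> None:
        inc = self.incidence.copy()
        if inc.index.duplicated().any():
            dups = inc.index[inc.index.duplicated()].tolist()
            raise CommunityError(f"duplicate site ids: {dups}")
        inc.columns = [canonical_label(c) for c in inc.columns]
        if pd.Index(inc.columns).duplicated().any():
            dups = pd.Index(inc.columns)
            raise CommunityError(
                f"duplicate species columns: {dups[dups.duplicated()].tolist()}"
            )
        values = inc.to_numpy()
        if not np.isfinite(values).all():
            raise CommunityError("incidence contains missing values")
        if ((values != 0) & (values != 1)).any():
            logger.warning("nonzero incidence values coerced to 1")
            inc = (inc != 0).astype(int)
        else:
            inc = inc.astype(int)
        empty = inc.sum(axis=1) == 0
        if empty.any():
            raise CommunityError(
                f"empty site (no species present): {inc.index[empty].tolist()}"
            )
        absent = inc.columns[inc.sum(axis=0) == 0].tolist()
        if absent:
            logger.warning("dropping %d species present at no site", len(absent))
            inc = inc.drop(columns=absent)
        self.incidence = inc
        if self.habitat is not None:
            hab = self.habitat.reindex(inc.index)
            if hab.isna().any():
                raise CommunityError("habitat labels missing for some sites")
            self.habitat = hab.astype(str)

    @property
    def site_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def n_sites(self) -> int:
        return len(self.incidence)

    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=1)

    def present_at(self, site_id) -> list[str]:
        row = self.incidence.loc[site_id]
        return list(row.index[row == 1])


@dataclass(frozen=True)
class SpeciesPool:
    """The set of species observed across all sites."""

    species: frozenset

    def __len__(self) -> int:
        return len(self.species)

    def sorted(self) -> list[str]:
        return sorted(self.species)


def read_community(path) -> CommunityMatrix:
    """Read a community matrix from CSV.

    Wide format: first column = site id, remaining columns = species (an
    optional ``habitat`` column is split off). Long format (columns
    ``site``, ``species``, optional ``habitat``) is pivoted. Nonzero
    incidence values are coerced to 1 with a logged warning.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CommunityError("community CSV needs a site column plus data")
    lower = [str(c).strip().lower() for c in df.columns]
    if "site" in lower and "species" in lower:
        return _read_long(df, lower)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    habitat = None
    hab_cols = [c for c in df.columns if str(c).strip().lower() == HABITAT_COLUMN]
    if hab_cols:
        habitat = df[hab_cols[0]].astype(str)
        df = df.drop(columns=hab_cols)
    df = df.apply(pd.to_numeric)
    return CommunityMatrix(incidence=df, habitat=habitat)


def _read_long(df: pd.DataFrame, lower: list[str]) -> CommunityMatrix:
    cols = dict(zip(lower, df.columns))
    site_c, sp_c = cols["site"], cols["species"]
    habitat = None
    if HABITAT_COLUMN in cols:
        hab = df[[site_c, cols[HABITAT_COLUMN]]].drop_duplicates()
        if hab[site_c].duplicated().any():
            raise CommunityError("conflicting habitat labels for a site")
        habitat = hab.set_index(site_c)[cols[HABITAT_COLUMN]]
        habitat.index = habitat.index.astype(str)
    wide = pd.crosstab(df[site_c].astype(str), df[sp_c])
    wide = (wide > 0).astype(int)
    wide.index.name = site_c
    return CommunityMatrix(incidence=wide, habitat=habitat)


def write_community(cm: CommunityMatrix, path) -> None:
    out = cm.incidence.copy()
    if cm.habitat is not None:
        out.insert(0, HABITAT_COLUMN, cm.habitat)
    out.index.name = "site"
    out.to_csv(path)


def union_subplots(subplots: list[CommunityMatrix]) -> CommunityMatrix:
    """Elementwise OR of subplot incidences recorded for the same sites."""
    if not subplots:
        raise CommunityError("no subplots given")
    base_sites = set(subplots[0].site_ids)
    for sp in subplots[1:]:
        if set(sp.site_ids) != base_sites:
            raise CommunityError(
                "subplots cover different site sets: "
                f"{sorted(base_sites ^ set(sp.site_ids))}"
            )
    all_species = sorted({s for sp in subplots for s in sp.species_names})
    order = subplots[0].site_ids
    acc = pd.DataFrame(0, index=order, columns=all_species)
    for sp in subplots:
        aligned = sp.incidence.reindex(index=order, columns=all_species, fill_value=0)
        acc = acc | aligned.astype(bool)
    habitat = subplots[0].habitat
    return CommunityMatrix(incidence=acc.astype(int), habitat=habitat)


def species_pool(cm: CommunityMatrix) -> SpeciesPool:
    """Pool = union of species over all sites (columns with ≥1 occurrence)."""
    present = cm.incidence.columns[cm.incidence.sum(axis=0) >= 1]
    return SpeciesPool(species=frozenset(present))
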