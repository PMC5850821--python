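"""Strain-by-site presence/absence matrix container.

The central data structure of the pipeline: rows are unique transposon
sites (novel insertions, ``_NR``, and annotated reference positions,
``_R``), columns are strains, and cells are 1 (present), 0 (absent) or
NA (insufficient evidence).  Reference sites additionally carry a class:
*active* (absent in at least one strain — evidence of excision) or
*monomorphic* (present in every scored strain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INSERTION = "insertion"
REFERENCE = "reference"

SITE_COLUMNS = ["chrom", "position", "family", "te_class", "site_type", "ref_class"]


def make_site_id(chrom: str, position: int, family: str, site_type: str) -> str:
    suffix = "NR" if site_type == INSERTION else "R"
    return f"{chrom}_{int(position)}_{family}_{suffix}"


@dataclass
class SiteMatrix:
    """Site metadata plus the strain-by-site score matrix.

    Parameters
    ----------
    sites:
        Indexed by site id, columns ``chrom, position, family, te_class,
        site_type, ref_class``; ``ref_class`` is ``active``/``monomorphic``
        for reference sites and NA for insertion sites.
    values:
        Indexed by site id (same order as ``sites``), one float column per
        strain with values 0.0, 1.0 or NaN.
    """

    sites: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.values.index):
            self.values = self.values.loc[self.sites.index]
        if not self.sites.index.is_unique:
            raise ValueError("site ids must be unique")

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    def insertion_ids(self) -> pd.Index:
        return self.sites.index[self.sites["site_type"] == INSERTION]

    def reference_ids(self) -> pd.Index:
        return self.sites.index[self.sites["site_type"] == REFERENCE]

    def active_reference_ids(self) -> pd.Index:
        mask = (self.sites["site_type"] == REFERENCE) & (self.sites["ref_class"] == "active")
        return self.sites.index[mask]

    def monomorphic_ids(self) -> pd.Index:
        mask = (self.sites["site_type"] == REFERENCE) & (self.sites["ref_class"] == "monomorphic")
        return self.sites.index[mask]

    def subset(self, site_ids) -> "SiteMatrix":
        return SiteMatrix(self.sites.loc[site_ids].copy(), self.values.loc[site_ids].copy())

    def sorted(self) -> "SiteMatrix":
        """Canonical ordering: by chrom, position, family, then strain name."""
        order = self.sites.sort_values(["chrom", "position", "family", "site_type"]).index
        vals = self.values.loc[order, sorted(self.values.columns)]
        return SiteMatrix(self.sites.loc[order], vals)

    def equals(self, other: "SiteMatrix") -> bool:
        a, b = self.sorted(), other.sorted()
        if list(a.sites.index) != list(b.sites.index):
            return False
        if list(a.values.columns) != list(b.values.columns):
            return False
        va, vb = a.values.to_numpy(float), b.values.to_numpy(float)
        both_nan = np.isnan(va) & np.isnan(vb)
        return bool(np.all(both_nan | (va == vb)))
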