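"""Desikan–Killiany region atlas: names, lobe groupings, and profile set.

The packaged atlas lists the 52 bilateral-combined regions used throughout
the pipeline (34 cortical parcels, 5 corpus-callosum segments, 9 subcortical
structures, 4 ventricular measures).  The default effect-size *profile set*
is the 48 non-ventricular regions; ventricles are kept for normalization and
factor analysis but excluded from the age/fitness effect profiles because
their volumes grow, rather than shrink, with age.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

_HEMI_PREFIXES = ("Left-", "Right-")


@dataclass(frozen=True)
class ROIAtlas:
    """Region table with lobe/group labels and hemisphere pairing flags."""

    table: pd.DataFrame = field(repr=False)

    @property
    def regions(self) -> list[str]:
        return list(self.table["region"])

    @property
    def profile_regions(self) -> list[str]:
        """Regions in the effect-size profile set (48 by default)."""
        return list(self.table.loc[self.table["in_profile"].astype(bool), "region"])

    @property
    def paired_regions(self) -> list[str]:
        return list(self.table.loc[self.table["paired"].astype(bool), "region"])

    @property
    def midline_regions(self) -> list[str]:
        return list(self.table.loc[~self.table["paired"].astype(bool), "region"])

    def group_of(self, region: str) -> str:
        row = self.table.loc[self.table["region"] == region]
        if row.empty:
            raise KeyError(f"unknown region: {region!r}")
        return str(row["group"].iloc[0])

    def fs_name_map(self) -> dict[str, str]:
        """Map FreeSurfer structure tokens to atlas region names.

        Bilateral subcortical structures are keyed with their ``Left-`` and
        ``Right-`` prefixes; cortical parcels with their bare aparc labels
        (hemisphere comes from the file they are read from).
        """
        mapping: dict[str, str] = {}
        for _, row in self.table.iterrows():
            fs = str(row["fs_name"])
            if bool(row["paired"]) and not fs.islower():
                for pre in _HEMI_PREFIXES:
                    mapping[pre + fs] = str(row["region"])
            else:
                mapping[fs] = str(row["region"])
        return mapping


def load_atlas() -> ROIAtlas:
    """Load the packaged 52-region atlas."""
    ref = importlib.resources.files("agefit.data") / "dk_atlas.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    table["paired"] = table["paired"].astype(bool)
    table["in_profile"] = table["in_profile"].astype(bool)
    return ROIAtlas(table=table)


def hemi_columns(atlas: ROIAtlas) -> list[str]:
    """Column names of the native (hemisphere-resolved) volume table."""
    cols: list[str] = []
    for _, row in atlas.table.iterrows():
        if row["paired"]:
            cols.extend([f"lh_{row['region']}", f"rh_{row['region']}"])
        else:
            cols.append(str(row["region"]))
    return cols
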