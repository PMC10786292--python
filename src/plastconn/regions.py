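"""Region tables for the bilateral language parcellation.

A :class:`RegionTable` lists the nodes of the connectome: cortical language
regions in each hemisphere plus corpus-callosum (CC) waypoint regions.  The
CC regions are used as a bottleneck through which interhemispheric
connectivity is approximated, because direct cortico-cortical tractography
across hemispheres is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

HEMISPHERES = ("L", "R")
SYSTEMS = ("IFG", "TL", "IPL", "aCC", "pCC")
CC_SYSTEMS = ("aCC", "pCC")


class RegionTableError(ValueError):
    """Raised when a region table fails validation."""


@dataclass(frozen=True)
class RegionTable:
    """Validated table of connectome regions.

    Parameters
    ----------
    frame
        DataFrame with columns ``region_id``, ``hemisphere`` (L/R) and
        ``system`` (IFG/TL/IPL/aCC/pCC).  Row order defines matrix order.
    """

    frame: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        f = self.frame
        missing = {"region_id", "hemisphere", "system"} - set(f.columns)
        if missing:
            raise RegionTableError(f"missing columns: {sorted(missing)}")
        dup = f["region_id"][f["region_id"].duplicated()]
        if len(dup):
            raise RegionTableError(f"duplicate region_id(s): {sorted(set(dup))}")
        bad_h = f.loc[~f["hemisphere"].isin(HEMISPHERES)]
        if len(bad_h):
            raise RegionTableError(
                f"unknown hemisphere in rows {list(bad_h['region_id'])}"
            )
        bad_s = f.loc[~f["system"].isin(SYSTEMS)]
        if len(bad_s):
            raise RegionTableError(f"unknown system in rows {list(bad_s['region_id'])}")
        for syst in SYSTEMS:
            nl = int(((f["system"] == syst) & (f["hemisphere"] == "L")).sum())
            nr = int(((f["system"] == syst) & (f["hemisphere"] == "R")).sum())
            if nl != nr:
                raise RegionTableError(
                    f"unbalanced hemispheres for system {syst}: {nl} L vs {nr} R"
                )
        if "is_cc" not in f.columns:
            f = f.copy()
            f["is_cc"] = f["system"].isin(CC_SYSTEMS)
            object.__setattr__(self, "frame", f)
        object.__setattr__(
            self, "_index", {r: i for i, r in enumerate(f["region_id"])}
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def region_ids(self) -> list[str]:
        return list(self.frame["region_id"])

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    def position(self, region_id: str) -> int:
        try:
            return self._index[region_id]
        except KeyError:
            raise KeyError(f"unknown region {region_id!r}") from None

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._index

    def cortical_ids(self, hemisphere: str | None = None) -> list[str]:
        f = self.frame
        sel = ~f["is_cc"].to_numpy()
        if hemisphere is not None:
            sel = sel & (f["hemisphere"] == hemisphere).to_numpy()
        return list(f.loc[sel, "region_id"])

    def cc_ids(self, hemisphere: str | None = None) -> list[str]:
        f = self.frame
        sel = f["is_cc"].to_numpy().copy()
        if hemisphere is not None:
            sel = sel & (f["hemisphere"] == hemisphere).to_numpy()
        return list(f.loc[sel, "region_id"])

    def is_cc(self, region_id: str) -> bool:
        return bool(self.frame["is_cc"].iloc[self.position(region_id)])

    def hemisphere(self, region_id: str) -> str:
        return str(self.frame["hemisphere"].iloc[self.position(region_id)])

    def write(self, path: str | Path) -> None:
        self.frame[["region_id", "hemisphere", "system"]].to_csv(
            path, sep="\t", index=False
        )


def read_region_table(path: str | Path) -> RegionTable:
    """Read a TSV region table (columns region_id, hemisphere, system)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return RegionTable(frame)


# Per-hemisphere region counts per system.  Totals (33 cortical + 5 CC per
# hemisphere) match the published bilateral language parcellation; the split
# across IFG/TL/IPL and aCC/pCC subregions is a synthetic stand-in for the
# atlas-level region list, which is not redistributable here.
_DEFAULT_COUNTS = {"IFG": 8, "TL": 15, "IPL": 10, "aCC": 2, "pCC": 3}


def language_parcellation() -> RegionTable:
    """The default bilateral language parcellation.

    33 cortical regions (inferior frontal gyrus, temporal lobe, inferior
    parietal lobe) plus 5 corpus-callosum regions per hemisphere, 76 regions
    in total.  Region identifiers are synthetic (``L_IFG_01`` ...), since the
    atlas-level names are not redistributable.
    """
    rows = []
    for hemi in HEMISPHERES:
        for syst, n in _DEFAULT_COUNTS.items():
            for k in range(1, n + 1):
                rows.append((f"{hemi}_{syst}_{k:02d}", hemi, syst))
    return RegionTable(pd.DataFrame(rows, columns=["region_id", "hemisphere", "system"]))


def toy_parcellation(n_cortical: int = 8, n_cc: int = 2) -> RegionTable:
    """A small generic bilateral table for simulation and testing.

    ``n_cortical`` cortical and ``n_cc`` CC regions per hemisphere; cortical
    regions are assigned round-robin to IFG/TL/IPL, CC regions to aCC/pCC.
    """
    rows = []
    cort_sys = ("IFG", "TL", "IPL")
    for hemi in HEMISPHERES:
        for k in range(n_cortical):
            rows.append((f"{hemi}_C{k:02d}", hemi, cort_sys[k % 3]))
        for k in range(n_cc):
            rows.append((f"{hemi}_CC{k:02d}", hemi, CC_SYSTEMS[k % 2]))
    return RegionTable(pd.DataFrame(rows, columns=["region_id", "hemisphere", "system"]))
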