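"""Regional volume ingestion and head-size normalization.

Volume tables are wide DataFrames: one row per participant (index = id),
one column per region, plus ``etiv`` (estimated total intracranial volume,
mm^3) and ``role`` ("analysis" or "reference").  Native tables keep the two
hemispheres separate (``lh_<Region>`` / ``rh_<Region>`` for paired regions,
bare names for midline structures); :func:`combine_hemispheres` sums the
pairs into the bilateral regions used by all statistics.

Head size is removed by the covariance method: for each region the volume
adjusted for eTIV is

    V_adj = V_nat - b * (eTIV - mean eTIV)

with ``b`` the least-squares slope of V_nat on eTIV over the normalization
sample.  A young reference group may be included in the slope estimation
(and nowhere else) to anchor the correction in a broader age range.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, load_atlas

logger = logging.getLogger(__name__)

META_COLUMNS = ("etiv", "role")

_ETIV_RE = re.compile(
    r"#\s*Measure\s+EstimatedTotalIntraCranialVol.*?,\s*([0-9.eE+-]+)\s*,\s*mm"
)


def region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _parse_stats_file(path: Path) -> tuple[float | None, dict[str, float]]:
    """Parse one FreeSurfer .stats file -> (etiv or None, {struct: volume})."""
    etiv = None
    col_headers: list[str] | None = None
    volumes: dict[str, float] = {}
    text = path.read_text().splitlines()
    for line in text:
        if line.startswith("#"):
            m = _ETIV_RE.match(line)
            if m:
                etiv = float(m.group(1))
            if line.startswith("# ColHeaders"):
                col_headers = line.removeprefix("# ColHeaders").split()
            continue
        if not line.strip():
            continue
        if col_headers is None:
            raise ValueError(f"{path}: data row before '# ColHeaders' line")
        fields = line.split()
        row = dict(zip(col_headers, fields))
        name = row.get("StructName")
        vol = row.get("Volume_mm3", row.get("GrayVol"))
        if name is None or vol is None:
            raise ValueError(f"{path}: no StructName/volume column")
        if name in volumes:
            raise ValueError(f"{path}: duplicate region {name!r}")
        volumes[name] = float(vol)
    return etiv, volumes


def read_freesurfer_stats(
    subject_dirs: dict[str, str | Path],
    atlas: ROIAtlas | None = None,
    role: str = "analysis",
) -> pd.DataFrame:
    """Read per-subject aseg/aparc ``.stats`` files into a native volume table.

    ``subject_dirs`` maps participant id to a directory containing
    ``aseg.stats`` and optionally ``lh.aparc.stats`` / ``rh.aparc.stats``.
    Structures not in the atlas are logged and dropped; a missing eTIV
    header is a hard error.
    """
    atlas = atlas or load_atlas()
    fs_map = atlas.fs_name_map()
    records = []
    for pid, d in subject_dirs.items():
        d = Path(d)
        rec: dict[str, float] = {}
        etiv = None
        for fname in ("aseg.stats", "lh.aparc.stats", "rh.aparc.stats"):
            fpath = d / fname
            if not fpath.exists():
                continue
            file_etiv, vols = _parse_stats_file(fpath)
            etiv = etiv if file_etiv is None else file_etiv
            hemi = fname[:2] if fname.startswith(("lh", "rh")) else None
            for struct, vol in vols.items():
                if hemi is not None:
                    region = fs_map.get(struct)
                    col = f"{hemi}_{region}" if region else None
                else:
                    region = fs_map.get(struct)
                    if region is None:
                        col = None
                    elif struct.startswith("Left-"):
                        col = f"lh_{region}"
                    elif struct.startswith("Right-"):
                        col = f"rh_{region}"
                    else:
                        col = region
                if col is None:
                    logger.info("%s: dropping unmapped structure %r", fpath, struct)
                    continue
                if col in rec:
                    raise ValueError(f"{fpath}: duplicate region {struct!r}")
                rec[col] = vol
        if etiv is None:
            raise ValueError(f"subject {pid}: no EstimatedTotalIntraCranialVol header")
        rec["etiv"] = etiv
        records.append(pd.Series(rec, name=pid))
    table = pd.DataFrame(records)
    table.index.name = "id"
    table["role"] = role
    return table


def combine_hemispheres(table: pd.DataFrame, atlas: ROIAtlas | None = None) -> pd.DataFrame:
    """Sum left+right volumes for paired regions; pass midline through."""
    atlas = atlas or load_atlas()
    out = pd.DataFrame(index=table.index)
    for _, row in atlas.table.iterrows():
        region = str(row["region"])
        if row["paired"]:
            lh, rh = f"lh_{region}", f"rh_{region}"
            if lh not in table.columns or rh not in table.columns:
                missing = [c for c in (lh, rh) if c not in table.columns]
                raise ValueError(f"missing hemisphere column(s) {missing} for {region!r}")
            out[region] = table[lh] + table[rh]
        else:
            if region not in table.columns:
                raise ValueError(f"missing midline region {region!r}")
            out[region] = table[region]
    for meta in META_COLUMNS:
        if meta in table.columns:
            out[meta] = table[meta]
    return out


def adjust_volume(table: pd.DataFrame, include_reference: bool = True) -> pd.DataFrame:
    """Apply the eTIV covariance correction to every region column.

    The regression slope and the mean eTIV are estimated over the
    *normalization sample*: all rows when ``include_reference`` is true,
    otherwise analysis rows only.  The correction itself is applied to all
    rows.  The per-region slopes are stored in ``result.attrs["slopes"]``.
    """
    if "etiv" not in table.columns:
        raise ValueError("table must carry an 'etiv' column")
    if include_reference or "role" not in table.columns:
        norm = table
    else:
        norm = table.loc[table["role"] == "analysis"]
    etiv_n = norm["etiv"].to_numpy(float)
    if np.ptp(etiv_n) == 0:
        raise ValueError("zero variance in eTIV: slope undefined")
    etiv_mean = etiv_n.mean()
    centered = etiv_n - etiv_mean
    denom = centered @ centered
    out = table.copy()
    slopes: dict[str, float] = {}
    for col in region_columns(table):
        v = norm[col].to_numpy(float)
        b = float(centered @ (v - v.mean()) / denom)
        slopes[col] = b
        out[col] = table[col] - b * (table["etiv"] - etiv_mean)
    out.attrs["slopes"] = slopes
    out.attrs["etiv_mean"] = float(etiv_mean)
    return out


def analysis_volumes(table: pd.DataFrame) -> pd.DataFrame:
    """Region columns of analysis-role rows (reference rows dropped)."""
    if "role" in table.columns:
        table = table.loc[table["role"] == "analysis"]
    return table[region_columns(table)]
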