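"""Readers/writers for the three tabular input dialects and the cohort join.

Three inputs are consumed:

* region-level morphometry in the FreeSurfer ``aparcstats2table`` dialect
  (one row per subject, columns ``<lh|rh>_<region>_<metric>``),
* hemisphere-level folding tables (total pial area, exposed area,
  average thickness) as produced by cortical-folding toolboxes,
* a metadata CSV with subject IDs, age, sex, group, dataset, scanning
  site and session.

All morphometry ends up in one tidy representation: a DataFrame with
columns ``subject_id, hemisphere, region, metric, value`` wrapped in
:class:`MorphometryTable`.  Values for thickness/area/volume must be
strictly positive (they are log-transformed downstream).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DK_REGIONS",
    "CANONICAL_METRICS",
    "FormatError",
    "MorphometryTable",
    "Cohort",
    "read_aparc_table",
    "read_folding_table",
    "read_metadata",
    "join_cohort",
    "write_morphometry",
    "read_morphometry",
]

#: the 34 cortical labels of the Desikan-Killiany parcellation (one hemisphere)
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

#: file-dialect metric token -> canonical metric name carrying units
METRIC_ALIASES = {
    "thickness": "thickness_mm",
    "volume": "volume_mm3",
    "area": "area_mm2",
    "thickness_mm": "thickness_mm",
    "volume_mm3": "volume_mm3",
    "area_mm2": "area_mm2",
}

CANONICAL_METRICS = (
    "thickness_mm", "volume_mm3", "area_mm2",
    "total_pial_area_mm2", "exposed_area_mm2", "avg_thickness_mm",
    "K", "I", "S",
)

#: metrics measured at whole-hemisphere level (region label "hemisphere")
HEMISPHERE_METRICS = ("total_pial_area_mm2", "exposed_area_mm2", "avg_thickness_mm", "K", "I", "S")

_HEMI_ALIASES = {"lh": "left", "rh": "right", "left": "left", "right": "right", "l": "left", "r": "right"}

_SEX_MAP = {
    "f": "female", "m": "male", "female": "female", "male": "male",
    "0": "female", "1": "male", "w": "female",
}

META_COLUMNS = ("subject_id", "age", "sex", "group", "dataset", "site", "session")


class FormatError(ValueError):
    """Raised when an input table does not match its expected dialect."""


@dataclass
class MorphometryTable:
    """Tidy morphometry: one row per (subject, hemisphere, region, metric)."""

    data: pd.DataFrame

    COLUMNS = ("subject_id", "hemisphere", "region", "metric", "value")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"morphometry table missing columns: {missing}")
        self.data = self.data.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        dup = self.data.duplicated(subset=["subject_id", "hemisphere", "region", "metric"])
        if dup.any():
            rows = self.data.loc[dup, ["subject_id", "region", "metric"]].head(5)
            raise FormatError(f"duplicate (subject, hemisphere, region, metric) records, e.g.\n{rows}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    def concat(self, other: "MorphometryTable") -> "MorphometryTable":
        return MorphometryTable(pd.concat([self.data, other.data], ignore_index=True))

    def select(self, metric: str | None = None, region: str | None = None,
               hemisphere: str | None = None) -> pd.DataFrame:
        d = self.data
        if metric is not None:
            d = d[d["metric"] == metric]
        if region is not None:
            d = d[d["region"] == region]
        if hemisphere is not None:
            d = d[d["hemisphere"] == hemisphere]
        return d

    def targets(self) -> list[tuple[str, str, str]]:
        """All (region, hemisphere, metric) combinations present."""
        cols = ["region", "hemisphere", "metric"]
        return [tuple(t) for t in self.data[cols].drop_duplicates().itertuples(index=False)]


@dataclass
class Cohort:
    """Joined morphometry + metadata with a report of dropped subjects."""

    morphometry: MorphometryTable
    meta: pd.DataFrame
    join_report: dict = field(default_factory=dict)

    def __post_init__(self):
        morph_ids = set(self.morphometry.data["subject_id"])
        meta_ids = set(self.meta["subject_id"])
        if morph_ids - meta_ids:
            raise FormatError(f"morphometry subjects without metadata: {sorted(morph_ids - meta_ids)[:5]}")

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    def subset(self, subject_ids) -> "Cohort":
        ids = set(subject_ids)
        morph = MorphometryTable(self.morphometry.data[self.morphometry.data["subject_id"].isin(ids)])
        meta = self.meta[self.meta["subject_id"].isin(ids)].reset_index(drop=True)
        return Cohort(morph, meta, dict(self.join_report))

    def controls(self) -> "Cohort":
        return self.subset(self.meta.loc[self.meta["group"] == "control", "subject_id"])

    def patients(self) -> "Cohort":
        return self.subset(self.meta.loc[self.meta["group"] != "control", "subject_id"])

    def aligned(self, region: str, hemisphere: str, metric: str) -> pd.DataFrame:
        """Meta joined with the value column of one (region, hemi, metric)."""
        vals = self.morphometry.select(metric=metric, region=region, hemisphere=hemisphere)
        merged = self.meta.merge(vals[["subject_id", "value"]], on="subject_id", how="inner")
        return merged


def _read_delimited(path) -> pd.DataFrame:
    """Auto-detect tab vs comma delimiter."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)


def _parse_aparc_column(col: str) -> tuple[str, str, str] | None:
    """Return (hemisphere, region, metric_token) or None for non-region columns."""
    parts = col.strip().split("_")
    if len(parts) < 3:
        return None
    hemi = _HEMI_ALIASES.get(parts[0].lower())
    metric = parts[-1].lower()
    region = "_".join(parts[1:-1]).lower()
    if hemi is None or region not in DK_REGIONS:
        return None
    return hemi, region, metric


def read_aparc_table(path, hemisphere: str | None = None, metric: str | None = None) -> MorphometryTable:
    """Read an ``aparcstats2table`` export into tidy morphometry.

    Parameters
    ----------
    path : path or file-like
        Tab- or comma-delimited file; first column the subject id (its
        header is the FreeSurfer table label, e.g. ``lh.aparc.thickness``),
        remaining columns ``<lh|rh>_<region>_<metric>``.
    hemisphere, metric : str, optional
        If given, validated against what the column names declare.

    Unknown/summary columns (``eTIV``, ``BrainSegVolNotVent``,
    ``lh_MeanThickness_thickness`` ...) are skipped with a log message.
    """
    raw = _read_delimited(path)
    if raw.shape[1] < 2:
        raise FormatError("aparc table needs a subject column plus at least one region column")
    subject_col = raw.columns[0]
    subjects = raw[subject_col].astype(str).str.strip()
    dup = subjects[subjects.duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate subject ids: {sorted(dup)}")

    records = []
    skipped = []
    want_hemi = _HEMI_ALIASES.get(hemisphere.lower()) if hemisphere else None
    for col in raw.columns[1:]:
        parsed = _parse_aparc_column(col)
        if parsed is None:
            skipped.append(col)
            continue
        hemi, region, metric_token = parsed
        canon = METRIC_ALIASES.get(metric_token)
        if canon is None or (metric and canon != METRIC_ALIASES.get(metric.lower(), metric)):
            skipped.append(col)
            continue
        if want_hemi and hemi != want_hemi:
            skipped.append(col)
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.argmax(vals.isna().to_numpy()))
            raise FormatError(f"non-numeric cell in column {col!r}, row {bad + 2} "
                              f"(value {raw[col].iloc[bad]!r})")
        records.append(pd.DataFrame({
            "subject_id": subjects, "hemisphere": hemi, "region": region,
            "metric": canon, "value": vals.to_numpy(dtype=float),
        }))
    if skipped:
        logger.info("read_aparc_table: skipped %d non-region column(s): %s", len(skipped), skipped)
    if not records:
        raise FormatError("no recognisable <hemi>_<region>_<metric> columns found")
    return MorphometryTable(pd.concat(records, ignore_index=True))


_FOLDING_ALIASES = {
    "total_pial_area": "total_pial_area_mm2",
    "totalarea": "total_pial_area_mm2",
    "pialarea": "total_pial_area_mm2",
    "at": "total_pial_area_mm2",
    "exposed_area": "exposed_area_mm2",
    "smoothpialarea": "exposed_area_mm2",
    "ae": "exposed_area_mm2",
    "avg_thickness": "avg_thickness_mm",
    "avgcortthickness": "avg_thickness_mm",
    "thickness": "avg_thickness_mm",
    "t": "avg_thickness_mm",
}


def read_folding_table(path) -> MorphometryTable:
    """Read a folding-toolbox hemisphere table.

    Expected columns: ``subject_id``, ``hemisphere``, ``total_pial_area``,
    ``exposed_area``, ``avg_thickness`` (common toolbox aliases accepted).
    Output rows carry region label ``"hemisphere"``.
    """
    raw = _read_delimited(path)
    cols = {c.lower().strip(): c for c in raw.columns}
    sid_col = next((cols[k] for k in ("subject_id", "subject", "subjid", "id") if k in cols), None)
    hemi_col = next((cols[k] for k in ("hemisphere", "hemi") if k in cols), None)
    if sid_col is None or hemi_col is None:
        raise FormatError("folding table requires subject_id and hemisphere columns")
    metric_cols = {}
    for key, orig in cols.items():
        canon = _FOLDING_ALIASES.get(key.replace("-", "_"))
        if canon:
            metric_cols[canon] = orig
    missing = [m for m in ("total_pial_area_mm2", "exposed_area_mm2", "avg_thickness_mm")
               if m not in metric_cols]
    if missing:
        raise FormatError(f"folding table missing measure columns for: {missing}")

    records = []
    hemis = raw[hemi_col].astype(str).str.strip().str.lower().map(_HEMI_ALIASES)
    if hemis.isna().any():
        raise FormatError(f"unrecognised hemisphere label(s): "
                          f"{sorted(raw[hemi_col][hemis.isna()].unique())}")
    for canon, orig in metric_cols.items():
        vals = pd.to_numeric(raw[orig], errors="coerce")
        if vals.isna().any():
            bad = int(np.argmax(vals.isna().to_numpy()))
            raise FormatError(f"non-numeric cell in column {orig!r}, row {bad + 2}")
        records.append(pd.DataFrame({
            "subject_id": raw[sid_col].astype(str).str.strip(),
            "hemisphere": hemis.to_numpy(),
            "region": "hemisphere", "metric": canon,
            "value": vals.to_numpy(dtype=float),
        }))
    return MorphometryTable(pd.concat(records, ignore_index=True))


def read_metadata(path) -> pd.DataFrame:
    """Read the metadata CSV (subject_id, age, sex, group, dataset, site, session).

    Column matching is case-insensitive and order-free; ``sex`` is
    normalised to {female, male} from F/M, 0/1 or spelled-out labels;
    ``age`` is parsed as real years.  Ages outside the normative support
    [5, 95] trigger a warning, not an error.
    """
    raw = _read_delimited(path)
    cols = {c.lower().strip(): c for c in raw.columns}
    aliases = {"subject_id": ("subject_id", "subject", "subjid", "id", "participant_id")}
    rename = {}
    for want in META_COLUMNS:
        cands = aliases.get(want, (want,))
        found = next((cols[c] for c in cands if c in cols), None)
        if found is None:
            raise FormatError(f"missing column: {want}")
        rename[found] = want
    meta = raw.rename(columns=rename).loc[:, list(META_COLUMNS)].copy()
    meta["subject_id"] = meta["subject_id"].astype(str).str.strip()

    age = pd.to_numeric(meta["age"], errors="coerce")
    if age.isna().any():
        bad = int(np.argmax(age.isna().to_numpy()))
        raise FormatError(f"unparseable age at row {bad + 2}: {meta['age'].iloc[bad]!r}")
    meta["age"] = age.astype(float)
    if ((meta["age"] < 5) | (meta["age"] > 95)).any():
        logger.warning("metadata contains ages outside the normative range [5, 95]")

    sex = meta["sex"].astype(str).str.strip().str.lower().map(_SEX_MAP)
    if sex.isna().any():
        bad = sorted(meta["sex"][sex.isna()].astype(str).unique())
        raise FormatError(f"unrecognised sex code(s): {bad}")
    meta["sex"] = sex
    for c in ("group", "dataset", "site", "session"):
        meta[c] = meta[c].astype(str).str.strip()
    meta["group"] = meta["group"].str.lower()

    # multiple sessions: keep the first by sort order, warn
    meta = meta.sort_values(["subject_id", "session"], kind="stable")
    dup = meta.duplicated(subset="subject_id")
    if dup.any():
        logger.warning("multiple sessions for %d subject(s); keeping the first session per subject",
                       int(meta.loc[dup, "subject_id"].nunique()))
        meta = meta[~dup]
    return meta.reset_index(drop=True)


def join_cohort(morph: MorphometryTable, meta: pd.DataFrame) -> Cohort:
    """Inner-join morphometry and metadata on subject_id.

    Subjects present in only one input are dropped and listed in the
    cohort's ``join_report``; an empty intersection is an error.
    """
    morph_ids = set(morph.data["subject_id"])
    meta_ids = set(meta["subject_id"])
    common = morph_ids & meta_ids
    if not common:
        raise FormatError("no subjects in common between morphometry and metadata")
    report = {
        "n_joined": len(common),
        "dropped_morphometry_only": sorted(morph_ids - meta_ids),
        "dropped_metadata_only": sorted(meta_ids - morph_ids),
    }
    if report["dropped_morphometry_only"] or report["dropped_metadata_only"]:
        logger.info("join_cohort: dropped %d morphometry-only and %d metadata-only subject(s)",
                    len(report["dropped_morphometry_only"]), len(report["dropped_metadata_only"]))
    kept_morph = MorphometryTable(morph.data[morph.data["subject_id"].isin(common)])
    kept_meta = meta[meta["subject_id"].isin(common)].reset_index(drop=True)
    if kept_morph.data["value"].isna().any():
        raise FormatError("NaN morphometry values after join")
    return Cohort(kept_morph, kept_meta, report)


def write_morphometry(table: MorphometryTable, path) -> None:
    """Write tidy morphometry CSV (full float precision, round-trip safe)."""
    table.data.to_csv(path, index=False)


def read_morphometry(path) -> MorphometryTable:
    """Read a tidy morphometry CSV written by :func:`write_morphometry`."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return MorphometryTable(df)
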