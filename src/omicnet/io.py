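"""Reading, QC and encoding of omic abundance tables and sample metadata.

Abundance tables are delimited text with one header row of feature IDs and a
first column of sample IDs (orientation is declared, never guessed). Protein
feature identity is ``display_name|platform_barcode`` — the same protein name
measured by two aptamer reagents yields two distinct features. Metabolite
tables may contain missing cells; proteins (RFU readouts) are complete and
strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKENS: tuple[str, ...] = ("", "NA", "NaN", "nan")
BARCODE_SEP = "|"

GROUPS = ("ACPA_NEG", "ACPA_POS", "CONTROL")
SEXES = ("F", "M")
SMOKING_LEVELS = ("NEVER_FORMER", "CURRENT", "UNKNOWN")
MED_FLAGS = ("med_prednisone", "med_bdmard", "med_csdmard", "med_mtx")
CLINICAL_MARKERS = ("esr", "crp", "das28crp")

METADATA_COLUMNS = (
    "group",
    "sex",
    "age",
    "bmi",
    "smoking",
    *MED_FLAGS,
    *CLINICAL_MARKERS,
)


class SmokingMode(str, Enum):
    """How samples with unknown smoking history enter a design matrix."""

    DROP_UNKNOWN = "drop_unknown"  # regression convention: exclude them
    UNKNOWN_LEVEL = "unknown_level"  # ML convention: Unknown is its own level


class Orientation(str, Enum):
    SAMPLES_BY_FEATURES = "samples_by_features"
    FEATURES_BY_SAMPLES = "features_by_samples"


@dataclass(frozen=True)
class OmicsMatrix:
    """Samples × features abundance table with per-feature metadata.

    ``values`` holds one row per sample and one column per feature; missing
    cells are NaN.  ``feature_info`` is indexed by feature ID with columns
    ``kind`` (protein/metabolite), ``display_name`` and ``platform_barcode``.
    """

    values: pd.DataFrame
    feature_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if not self.values.columns.equals(self.feature_info.index):
            raise ValueError("feature_info index must match value columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True where the cell is missing)."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values, self.feature_info.loc[values.columns])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def _parse_feature_info(feature_ids: Sequence[str], omic_kind: str) -> pd.DataFrame:
    names, barcodes = [], []
    for fid in feature_ids:
        if omic_kind == "protein" and BARCODE_SEP in fid:
            name, _, barcode = fid.rpartition(BARCODE_SEP)
        else:
            name, barcode = fid, ""
        names.append(name)
        barcodes.append(barcode)
    return pd.DataFrame(
        {"kind": omic_kind, "display_name": names, "platform_barcode": barcodes},
        index=pd.Index(feature_ids, name="feature_id"),
    )


def load_feature_table(
    path: str | Path,
    omic_kind: str,
    exclusion_list: Iterable[str] | None = None,
    *,
    orientation: Orientation = Orientation.SAMPLES_BY_FEATURES,
    na_tokens: Sequence[str] = NA_TOKENS,
    sep: str | None = None,
) -> OmicsMatrix:
    """Read an abundance table, dropping excluded features.

    Empty cells and declared NA tokens become missing values. Duplicate sample
    or feature IDs and non-numeric cells are hard errors.
    """
    if omic_kind not in ("protein", "metabolite"):
        raise ValueError(f"omic_kind must be protein or metabolite, got {omic_kind!r}")
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_header = sorted({h for h in header if header.count(h) > 1})
    if dup_header:
        # pandas would silently mangle duplicate column names
        raise ValueError(f"duplicate IDs in {path.name} header: {dup_header}")
    raw = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    if orientation == Orientation.FEATURES_BY_SAMPLES:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        raise ValueError(
            f"duplicate sample IDs in {path.name}: "
            f"{sorted(set(raw.index[raw.index.duplicated()]))}"
        )
    if raw.columns.has_duplicates:
        raise ValueError(
            f"duplicate feature IDs in {path.name}: "
            f"{sorted(set(raw.columns[raw.columns.duplicated()]))}"
        )

    na_set = set(na_tokens)
    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        cells = raw[col].str.strip()
        observed = ~cells.isin(na_set)
        try:
            values[observed.to_numpy(), j] = cells[observed].astype(float)
        except ValueError:
            for i, (ok, cell) in enumerate(zip(observed, cells)):
                if ok:
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric cell at sample {raw.index[i]!r}, "
                            f"feature {col!r}: {cell!r}"
                        ) from None
    frame = pd.DataFrame(values, index=raw.index, columns=raw.columns)

    excluded = set(exclusion_list or ())
    to_drop = [f for f in frame.columns if f in excluded]
    if to_drop:
        logger.info("dropped %d excluded features from %s", len(to_drop), path.name)
        frame = frame.drop(columns=to_drop)
    return OmicsMatrix(frame, _parse_feature_info(frame.columns, omic_kind))


def filter_by_missingness(
    m: OmicsMatrix, max_frac: float = 0.20
) -> tuple[OmicsMatrix, dict]:
    """Drop features missing in strictly more than ``max_frac`` of samples.

    A feature missing in exactly ``max_frac`` of samples is retained ("over
    20%" is a strict inequality). Returns the filtered matrix and a removal
    report.
    """
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError(f"max_frac must be in [0, 1], got {max_frac}")
    frac = m.values.isna().mean(axis=0)
    removed = frac.index[frac > max_frac].tolist()
    report = {
        "n_features_in": len(m.feature_ids),
        "n_removed": len(removed),
        "removed": removed,
        "max_frac": max_frac,
    }
    kept = m.values.drop(columns=removed)
    return OmicsMatrix(kept, m.feature_info.loc[kept.columns]), report


def scale_and_impute(m: OmicsMatrix, order: str = "scale_then_impute") -> OmicsMatrix:
    """Median-scale each feature to 1, then fill missing cells.

    Default order: divide each feature's observed values by their median
    (Metabolon "scaled imputed" convention), then impute missing cells with
    the minimum of the scaled observed values.  ``order="impute_then_scale"``
    swaps the two steps.
    """
    if order not in ("scale_then_impute", "impute_then_scale"):
        raise ValueError(f"unknown order {order!r}")
    vals = m.values.to_numpy(copy=True)
    all_missing = np.isnan(vals).all(axis=0)
    if all_missing.any():
        bad = [m.feature_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"features with no observed values (filter first): {bad}")
    if order == "scale_then_impute":
        med = np.nanmedian(vals, axis=0)
        if np.any(med == 0):
            raise ValueError("feature with zero median cannot be median-scaled")
        vals = vals / med
        fill = np.nanmin(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[1]]
    else:
        fill = np.nanmin(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[1]]
        med = np.median(vals, axis=0)
        if np.any(med == 0):
            raise ValueError("feature with zero median cannot be median-scaled")
        vals = vals / med
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return OmicsMatrix(out, m.feature_info)


def log_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Natural-log transform (for strictly positive RFU-style abundances)."""
    vals = m.values.to_numpy()
    if np.nanmin(vals) <= 0:
        raise ValueError("log transform requires strictly positive abundances")
    return m.with_values(np.log(m.values))


def preprocess_proteins(prot: OmicsMatrix, log: bool = True) -> OmicsMatrix:
    """Analysis-scale protein block: natural log of the RFU readout."""
    return log_transform(prot) if log else prot


def preprocess_metabolites(
    met: OmicsMatrix, max_missing_frac: float = 0.20, log: bool = True
) -> tuple[OmicsMatrix, dict]:
    """Analysis-scale metabolite block plus the QC removal report.

    Missingness filter (strictly over ``max_missing_frac``), median scaling
    to 1, minimum-value imputation, then (by default) natural log — linear
    models on the heavily right-skewed raw scale lose power and calibration.
    """
    kept, report = filter_by_missingness(met, max_missing_frac)
    ready = scale_and_impute(kept)
    if log:
        ready = log_transform(ready)
    return ready, report


def merge_omics(prot: OmicsMatrix, met: OmicsMatrix) -> OmicsMatrix:
    """Column-concatenate two omic blocks over the same sample set.

    Sample order follows the first argument; feature IDs must be disjoint.
    """
    sp, sm = set(prot.sample_ids), set(met.sample_ids)
    if sp != sm:
        raise ValueError(
            "sample sets differ: "
            f"only in first={sorted(sp - sm)}, only in second={sorted(sm - sp)}"
        )
    overlap = set(prot.feature_ids) & set(met.feature_ids)
    if overlap:
        raise ValueError(f"overlapping feature IDs across blocks: {sorted(overlap)}")
    met_aligned = met.values.loc[prot.values.index]
    values = pd.concat([prot.values, met_aligned], axis=1)
    info = pd.concat([prot.feature_info, met.feature_info])
    return OmicsMatrix(values, info)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample phenotype, demographics, medication flags, clinical markers.

    Wraps a validated DataFrame indexed by sample ID. Group is always present;
    ESR/CRP/DAS28-CRP may be missing; medication flags are never missing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise ValueError("duplicate sample IDs in metadata")
        missing = [c for c in METADATA_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad = set(f["group"]) - set(GROUPS)
        if bad or f["group"].isna().any():
            raise ValueError(f"invalid group labels: {sorted(map(str, bad))}")
        if not set(f["sex"]) <= set(SEXES):
            raise ValueError("sex must be F or M")
        if not set(f["smoking"]) <= set(SMOKING_LEVELS):
            raise ValueError(f"smoking must be one of {SMOKING_LEVELS}")
        for flag in MED_FLAGS:
            if f[flag].isna().any():
                raise ValueError(f"medication flag {flag} must never be missing")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        f = pd.read_csv(path, sep="\t", index_col=0)
        f.index = f.index.astype(str)
        for flag in MED_FLAGS:
            if flag in f.columns:
                f[flag] = f[flag].astype(bool)
        return cls(f)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def group_members(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])


VALID_INCLUDE = frozenset({"sex", "age", "bmi", "smoking", "meds", "phenotype"})


def encode_design(
    meta: SampleMetadata,
    include: Iterable[str] = ("sex", "age", "bmi", "smoking", "meds"),
    smoking_mode: SmokingMode = SmokingMode.DROP_UNKNOWN,
    *,
    full_indicators: bool | None = None,
    add_intercept: bool | None = None,
) -> pd.DataFrame:
    """Build a design matrix from sample metadata.

    ``DROP_UNKNOWN`` (regression mode) removes unknown-smoking samples and
    uses reference coding with an intercept; ``UNKNOWN_LEVEL`` (ML/network
    mode) keeps them, one-hot encoding smoking into three indicator columns
    and the phenotype into three indicator columns, with no intercept.
    """
    include = set(include)
    bad = include - VALID_INCLUDE
    if bad:
        raise ValueError(f"unknown include flags: {sorted(bad)}")
    if full_indicators is None:
        full_indicators = smoking_mode == SmokingMode.UNKNOWN_LEVEL
    if add_intercept is None:
        add_intercept = not full_indicators

    f = meta.frame
    if "smoking" in include and smoking_mode == SmokingMode.DROP_UNKNOWN:
        f = f[f["smoking"] != "UNKNOWN"]

    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["const"] = np.ones(len(f))
    if "sex" in include:
        if full_indicators:
            for lev in SEXES:
                cols[f"sex_{lev}"] = (f["sex"] == lev).astype(float).to_numpy()
        else:
            cols["sex_M"] = (f["sex"] == "M").astype(float).to_numpy()
    if "age" in include:
        cols["age"] = f["age"].astype(float).to_numpy()
    if "bmi" in include:
        cols["bmi"] = f["bmi"].astype(float).to_numpy()
    if "smoking" in include:
        if full_indicators:
            levels = SMOKING_LEVELS
            for lev in levels:
                cols[f"smoking_{lev}"] = (f["smoking"] == lev).astype(float).to_numpy()
        else:
            cols["smoking_CURRENT"] = (f["smoking"] == "CURRENT").astype(float).to_numpy()
    if "meds" in include:
        for flag in MED_FLAGS:
            cols[flag] = f[flag].astype(float).to_numpy()
    if "phenotype" in include:
        if full_indicators:
            for g in GROUPS:
                cols[f"group_{g}"] = (f["group"] == g).astype(float).to_numpy()
        else:
            for g in ("ACPA_NEG", "ACPA_POS"):
                cols[f"group_{g}"] = (f["group"] == g).astype(float).to_numpy()
    return pd.DataFrame(cols, index=f.index)
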