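"""Domain types and on-disk formats for the neonatal DBS metabolomics pipeline.

The central container is :class:`FeatureTable`: a samples x features intensity
matrix with explicit missingness (a missing cell means "not detected"; a
measured zero is a valid value distinct from missing), plus per-sample plate,
injection-order and QC annotations.  Tables are exchanged as tab-delimited
UTF-8 text; MS/MS spectra are exchanged as MGF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "FormatError",
    "ConfigError",
    "QC_FLAGS",
    "SEASONS",
    "FeatureTable",
    "SampleRecord",
    "SpectrumMS2",
    "AssocResult",
    "MatchThresholds",
    "read_feature_table",
    "write_feature_table",
    "read_sample_records",
    "write_sample_records",
    "read_mgf",
    "write_mgf",
    "read_assoc_results",
    "write_assoc_results",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


class ConfigError(ValueError):
    """Raised when a configuration value is outside its valid domain."""


QC_FLAGS = ("analytical", "external_control", "plate_pool")
SEASONS = ("winter", "spring", "summer", "autumn")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with explicit missingness.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with feature ids as columns.  ``NaN``
        encodes "not detected"; all present values must be non-negative
        (strictly positive for raw peak areas, but zero is tolerated as a
        measured value).
    plate
        Per-sample plate label (opaque categorical), aligned to the index.
    injection_order
        1-based injection position, unique within each plate.
    qc_flag
        One of ``analytical``, ``external_control``, ``plate_pool``.
    """

    intensities: pd.DataFrame
    plate: pd.Series
    injection_order: pd.Series
    qc_flag: pd.Series

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.intensities.columns.has_duplicates:
            raise FormatError("duplicate feature ids")
        for name in ("plate", "injection_order", "qc_flag"):
            s = getattr(self, name)
            if not s.index.equals(idx):
                setattr(self, name, s.reindex(idx))
                if getattr(self, name).isna().any():
                    raise FormatError(f"metadata column {name!r} does not cover all samples")
        bad = set(self.qc_flag.unique()) - set(QC_FLAGS)
        if bad:
            raise FormatError(f"unknown qc_flag values: {sorted(bad)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise FormatError("negative intensity")
        for plate, grp in self.injection_order.groupby(self.plate, observed=True):
            if grp.duplicated().any():
                raise FormatError(f"duplicate injection order within plate {plate!r}")
        if (self.injection_order < 1).any():
            raise FormatError("injection order must be a positive integer")

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is missing (not detected)."""
        return self.intensities.isna()

    def analytical(self) -> "FeatureTable":
        """Subset to analytical samples (QC rows dropped)."""
        keep = self.qc_flag == "analytical"
        return self.subset(self.intensities.index[keep])

    def qc_rows(self, kinds: Sequence[str] = ("external_control", "plate_pool")) -> "FeatureTable":
        keep = self.qc_flag.isin(kinds)
        return self.subset(self.intensities.index[keep])

    def subset(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            intensities=self.intensities.loc[ids].copy(),
            plate=self.plate.loc[ids].copy(),
            injection_order=self.injection_order.loc[ids].copy(),
            qc_flag=self.qc_flag.loc[ids].copy(),
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureTable":
        """Same annotations, new values (shape and index must match)."""
        if not intensities.index.equals(self.intensities.index):
            raise ValueError("sample index mismatch")
        return FeatureTable(
            intensities=intensities,
            plate=self.plate.copy(),
            injection_order=self.injection_order.copy(),
            qc_flag=self.qc_flag.copy(),
        )


@dataclass
class SampleRecord:
    """One subject: outcome, matching covariates, confounders.

    ``age_at_sampling`` is in days after birth (the heel-prick DBS is drawn
    days 3-8); ``gestational_age`` in weeks.  ``pcs`` are six genetic
    principal components; ``prs`` is a standardized polygenic score.
    ``age_at_diagnosis`` (years) is set for cases only and may be NaN.
    """

    sample_id: str
    group: str  # {"case", "control"}
    pair_id: str
    gestational_age: float
    age_at_sampling: float
    season: str
    birth_year: int
    family_history: int
    prs: float
    pcs: tuple[float, ...] = field(default_factory=tuple)
    age_at_diagnosis: float = math.nan

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise FormatError(f"group must be case/control, got {self.group!r}")
        if self.season not in SEASONS:
            raise FormatError(f"unknown season {self.season!r}")
        if self.family_history not in (0, 1):
            raise FormatError("family_history must be 0/1")


@dataclass
class SpectrumMS2:
    """An MS/MS spectrum: precursor m/z plus a peak list.

    Peaks are stored as an (n, 2) float array of (m/z, intensity), sorted by
    ascending m/z; the constructor sorts unsorted input.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: np.ndarray

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.ndim != 2 or peaks.shape[1] != 2 or peaks.shape[0] == 0:
            raise FormatError("peaks must be a non-empty (n, 2) array")
        if not np.all(np.isfinite(peaks)):
            raise FormatError("non-finite peak values")
        if np.any(peaks[:, 1] < 0):
            raise FormatError("negative peak intensity")
        if self.precursor_mz <= 0:
            raise FormatError("precursor m/z must be positive")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass
class AssocResult:
    """Per-feature association: effect estimate, Wald CI, p, BH q.

    ``estimate`` is an odds ratio for logistic modes and a beta for
    ``mode='linear'``.  ``quartile_level`` is set for quartile coding (2-4,
    with Q1 the implicit OR=1 reference).
    """

    feature_id: str
    mode: str  # {"continuous_per_sd", "binary_presence", "quartile", "linear"}
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    q: float = math.nan
    model_id: str = "model1"
    n_used: int = 0
    quartile_level: int | None = None
    flag: str = ""


@dataclass
class MatchThresholds:
    """Spectral library-search acceptance thresholds."""

    min_cosine: float = 0.7
    min_matched_peaks: int = 4
    parent_mass_tol: float = 0.05
    fragment_tol: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_cosine <= 1):
            raise ConfigError("min_cosine must be in (0, 1]")
        if self.min_matched_peaks < 1:
            raise ConfigError("min_matched_peaks must be >= 1")
        if self.parent_mass_tol <= 0 or self.fragment_tol <= 0:
            raise ConfigError("mass tolerances must be strictly positive")


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "plate", "injection_order", "qc_flag"]


def read_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read a wide tab-delimited intensity table plus its sample metadata.

    First column of the wide table is the sample id; remaining columns are
    feature ids.  Empty cells and ``NA`` encode missing (not detected).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    feature_cols = header[1:]
    if len(set(feature_cols)) != len(feature_cols):
        raise FormatError("duplicate feature ids in header")
    raw = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["", "NA"], keep_default_na=False)
    raw.columns = header  # undo any pandas duplicate-header mangling
    raw[raw.columns[0]] = raw[raw.columns[0]].astype(str)
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "sample_id"
    intens = raw.apply(pd.to_numeric).astype(float)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "plate": str})
    missing_cols = set(_META_COLS) - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("sample_id").loc[intens.index]
    return FeatureTable(
        intensities=intens,
        plate=meta["plate"],
        injection_order=meta["injection_order"].astype(int),
        qc_flag=meta["qc_flag"],
    )


def write_feature_table(table: FeatureTable, path: str | Path, metadata_path: str | Path) -> None:
    """Write the intensity table and sample metadata as two TSV files.

    Missing cells are written as empty strings (never zero-filled).
    """
    out = table.intensities.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="")
    meta = pd.DataFrame(
        {
            "sample_id": table.intensities.index,
            "plate": table.plate.values,
            "injection_order": table.injection_order.values,
            "qc_flag": table.qc_flag.values,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample-record I/O
# ---------------------------------------------------------------------------


def write_sample_records(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "group": r.group,
            "pair_id": r.pair_id,
            "gestational_age": r.gestational_age,
            "age_at_sampling": r.age_at_sampling,
            "season": r.season,
            "birth_year": r.birth_year,
            "family_history": r.family_history,
            "prs": r.prs,
            "age_at_diagnosis": r.age_at_diagnosis,
        }
        for k, pc in enumerate(r.pcs, start=1):
            row[f"pc{k}"] = pc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


def read_sample_records(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    pc_cols = sorted(
        (c for c in df.columns if c.startswith("pc") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                group=row["group"],
                pair_id=row["pair_id"],
                gestational_age=float(row["gestational_age"]),
                age_at_sampling=float(row["age_at_sampling"]),
                season=row["season"],
                birth_year=int(row["birth_year"]),
                family_history=int(row["family_history"]),
                prs=float(row["prs"]),
                pcs=tuple(float(row[c]) for c in pc_cols),
                age_at_diagnosis=float(row["age_at_diagnosis"])
                if "age_at_diagnosis" in df.columns and pd.notna(row["age_at_diagnosis"])
                else math.nan,
            )
        )
    return records


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Covariate frame indexed by sample id (design-matrix friendly)."""
    rows = {}
    for r in records:
        row = {
            "group": r.group,
            "pair_id": r.pair_id,
            "y": 1 if r.group == "case" else 0,
            "gestational_age": r.gestational_age,
            "age_at_sampling": r.age_at_sampling,
            "season": r.season,
            "birth_year": r.birth_year,
            "family_history": r.family_history,
            "prs": r.prs,
            "age_at_diagnosis": r.age_at_diagnosis,
        }
        for k, pc in enumerate(r.pcs, start=1):
            row[f"pc{k}"] = pc
        rows[r.sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[SpectrumMS2]:
    """Parse an MGF file into a list of spectra (peaks sorted by m/z)."""
    spectra: list[SpectrumMS2] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise FormatError(f"MGF block {i} lacks PEPMASS")
                title = str(params.get("title", f"spectrum_{i}"))
                mz = np.asarray(entry["m/z array"], dtype=float)
                inten = np.asarray(entry["intensity array"], dtype=float)
                if mz.size == 0:
                    raise FormatError(f"MGF block {title!r} has no peaks")
                spectra.append(
                    SpectrumMS2(
                        spectrum_id=title,
                        precursor_mz=float(params["pepmass"][0]),
                        peaks=np.column_stack([mz, inten]),
                    )
                )
    except FormatError:
        raise
    except Exception as exc:  # pyteomics raises assorted errors on bad blocks
        raise FormatError(f"malformed MGF: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[SpectrumMS2], path: str | Path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {"title": s.spectrum_id, "pepmass": s.precursor_mz},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Association-result I/O
# ---------------------------------------------------------------------------

_RESULT_COLS = [
    "feature_id",
    "mode",
    "estimate",
    "ci_low",
    "ci_high",
    "p",
    "q",
    "model_id",
    "n_used",
    "quartile_level",
    "flag",
]


def write_assoc_results(results: Sequence[AssocResult], path: str | Path) -> None:
    """Write association results as a TSV (full float precision)."""
    if not results:
        raise ValueError("no results to write")
    df = pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "mode": r.mode,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "q": r.q,
                "model_id": r.model_id,
                "n_used": r.n_used,
                "quartile_level": r.quartile_level,
                "flag": r.flag,
            }
            for r in results
        ],
        columns=_RESULT_COLS,
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_assoc_results(path: str | Path) -> list[AssocResult]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            AssocResult(
                feature_id=str(row["feature_id"]),
                mode=row["mode"],
                estimate=float(row["estimate"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p=float(row["p"]),
                q=float(row["q"]) if pd.notna(row["q"]) else math.nan,
                model_id=row["model_id"],
                n_used=int(row["n_used"]),
                quartile_level=int(row["quartile_level"]) if pd.notna(row["quartile_level"]) else None,
                flag=row["flag"] if pd.notna(row["flag"]) and row["flag"] != "" else "",
            )
        )
    return out
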