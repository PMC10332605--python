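"""Nested eDNA survey data: containers, long-format IO, and covariate preparation.

Detection data from eDNA surveys are nested: several qPCR replicates per
water sample, several water samples per site.  :class:`SurveyDataset` holds
this ragged three-level structure together with site- and sample-level
covariates.  Replicates with no usable result are coded as missing (NaN),
never as non-detections, so likelihood code can skip them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "IntegrityError",
    "DegenerateScaleError",
    "ReplicateRecord",
    "SurveyDataset",
    "read_long_csv",
    "write_long_csv",
    "attach_site_covariates",
    "relative_density",
    "aggregate_site_measurements",
    "standardize_covariates",
]

LONG_COLUMNS = ["site", "location", "sample", "replicate", "detection", "ct", "quality_override"]
_REQUIRED = ["site", "sample", "replicate"]
_RAW_SUFFIX = "__raw"


class SchemaError(ValueError):
    """Input table lacks required columns."""


class IntegrityError(ValueError):
    """Input rows violate domain constraints (duplicates, bad detection codes)."""


class DegenerateScaleError(ValueError):
    """Covariate has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class ReplicateRecord:
    """One qPCR replicate (one row of the long format)."""

    site_id: str
    sample_id: str
    replicate_index: int
    detection: float | None = None  # 0, 1 or None (missing)
    location_id: str | None = None
    ct: float | None = None
    quality_override: bool | None = None

    def __post_init__(self) -> None:
        if self.detection is not None and self.detection not in (0, 1):
            raise IntegrityError(f"detection must be 0, 1 or missing; got {self.detection!r}")
        if self.replicate_index < 1:
            raise IntegrityError("replicate_index is 1-based and must be >= 1")


@dataclass
class SurveyDataset:
    """Ragged three-level detection array plus covariates.

    ``detections[i][j]`` is a float array of 0/1/NaN for the replicates of
    sample *j* at site *i*.  Covariate frames are indexed by site id
    (``site_covariates``) or by ``(site, sample)`` (``sample_covariates``).
    ``standardization`` records the mean/SD used for each standardized
    covariate so effects can be reported on the natural scale.
    """

    site_ids: list[str]
    sample_ids: list[list[str]]
    detections: list[list[np.ndarray]]
    site_covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.site_ids) != len(set(self.site_ids)):
            raise IntegrityError("duplicate site ids")
        if not (len(self.site_ids) == len(self.sample_ids) == len(self.detections)):
            raise IntegrityError("ragged shapes inconsistent across levels")
        for sids, dets in zip(self.sample_ids, self.detections):
            if len(sids) != len(dets):
                raise IntegrityError("sample ids and detection arrays differ in length")
            for k, y in enumerate(dets):
                y = np.asarray(y, dtype=float)
                dets[k] = y
                bad = y[~np.isnan(y)]
                if bad.size and not np.isin(bad, (0.0, 1.0)).all():
                    raise IntegrityError("detections must be 0, 1 or missing")
        if len(self.site_covariates) and not set(self.site_covariates.index) >= set(self.site_ids):
            raise IntegrityError("site covariates missing rows for some sites")

    # -- shape summaries -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def samples_per_site(self) -> list[int]:
        return [len(s) for s in self.sample_ids]

    @property
    def replicates_per_sample(self) -> list[int]:
        return [len(y) for site in self.detections for y in site]

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_site)

    @property
    def n_replicates(self) -> int:
        return sum(self.replicates_per_sample)

    def totals(self) -> dict[str, int]:
        """Observed totals: positive samples/replicates over non-missing data."""
        pos_s = pos_r = n_r = 0
        for site in self.detections:
            for y in site:
                obs = y[~np.isnan(y)]
                n_r += obs.size
                pos_r += int(obs.sum())
                pos_s += int(obs.any())
        return {
            "n_sites": self.n_sites,
            "n_samples": self.n_samples,
            "n_replicates": n_r,
            "positive_samples": pos_s,
            "positive_replicates": pos_r,
        }

    # -- flat views used by the model fitters ----------------------------
    def flatten(self) -> dict[str, np.ndarray]:
        """Flat replicate-level arrays with index maps into samples and sites."""
        y, rep_sample, sample_site = [], [], []
        s = 0
        for i, site in enumerate(self.detections):
            for arr in site:
                y.append(arr)
                rep_sample.extend([s] * len(arr))
                sample_site.append(i)
                s += 1
        y = np.concatenate(y) if y else np.empty(0)
        return {
            "y": y,
            "rep_sample": np.asarray(rep_sample, dtype=np.intp),
            "sample_site": np.asarray(sample_site, dtype=np.intp),
        }

    def sample_covariate_values(self, name: str) -> np.ndarray:
        """Per-sample covariate vector; site-level covariates broadcast down."""
        if name in self.sample_covariates.columns:
            out = []
            for sid, samples in zip(self.site_ids, self.sample_ids):
                for smp in samples:
                    out.append(float(self.sample_covariates.loc[(sid, smp), name]))
            return np.asarray(out)
        if name in self.site_covariates.columns:
            per_site = self.site_covariates[name].reindex(self.site_ids).to_numpy(float)
            return np.repeat(per_site, self.samples_per_site)
        raise KeyError(f"covariate {name!r} not found at site or sample level")

    def site_covariate_values(self, name: str) -> np.ndarray:
        if name not in self.site_covariates.columns:
            raise KeyError(f"covariate {name!r} not found at site level")
        return self.site_covariates[name].reindex(self.site_ids).to_numpy(float)

    def copy(self) -> "SurveyDataset":
        return copy.deepcopy(self)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for sid, samples, dets in zip(self.site_ids, self.sample_ids, self.detections):
            for smp, arr in zip(samples, dets):
                for k, val in enumerate(arr, start=1):
                    rows.append(
                        {"site": sid, "sample": smp, "replicate": k,
                         "detection": "" if np.isnan(val) else int(val)}
                    )
        return pd.DataFrame(rows, columns=["site", "sample", "replicate", "detection"])


def _records_to_dataset(df: pd.DataFrame) -> SurveyDataset:
    site_ids: list[str] = []
    sample_ids: list[list[str]] = []
    detections: list[list[np.ndarray]] = []
    for site, site_df in df.groupby("site", sort=False):
        site_ids.append(str(site))
        sids, dets = [], []
        for sample, smp_df in site_df.groupby("sample", sort=False):
            smp_df = smp_df.sort_values("replicate")
            dup = smp_df["replicate"].duplicated()
            if dup.any():
                raise IntegrityError(
                    f"duplicate (site, sample, replicate) rows for {site}/{sample}"
                )
            sids.append(str(sample))
            dets.append(smp_df["detection"].to_numpy(dtype=float))
        sample_ids.append(sids)
        detections.append(dets)
    return SurveyDataset(site_ids, sample_ids, detections)


def read_long_csv(path: str | Path, *, detection_column: str = "detection") -> SurveyDataset:
    """Read one-row-per-replicate CSV into a validated :class:`SurveyDataset`.

    Required columns: ``site, sample, replicate`` plus either ``detection``
    or a ``ct`` column (the latter is kept for downstream calling; see
    :mod:`occuscale.qpcr`).  Row order determines site/sample ordering.
    """
    df = pd.read_csv(path, dtype={"site": str, "sample": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if detection_column not in df.columns:
        if "ct" in df.columns:
            raise SchemaError(
                "no detection column: raw ct values must first be called "
                "(occuscale.qpcr.assemble_histories)"
            )
        raise SchemaError(f"missing required columns: ['{detection_column}']")
    det = pd.to_numeric(df[detection_column], errors="coerce")
    valid = det.isna() | det.isin([0, 1])
    if not valid.all():
        bad = sorted(det[~valid].unique())
        raise IntegrityError(f"detection values outside {{0, 1, missing}}: {bad}")
    df = df.assign(detection=det)
    return _records_to_dataset(df)


def write_long_csv(dataset: SurveyDataset, path: str | Path) -> None:
    dataset.to_long().to_csv(path, index=False)


def attach_site_covariates(dataset: SurveyDataset, table: pd.DataFrame | str | Path,
                           key: str = "site") -> SurveyDataset:
    """Attach a site-keyed covariate table (CSV path or DataFrame)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, dtype={key: str})
    table = table.set_index(key) if key in table.columns else table
    out = dataset.copy()
    joined = table.reindex(out.site_ids)
    if joined.isna().any().any():
        raise IntegrityError("site covariate table missing rows for some sites")
    if len(out.site_covariates):
        out.site_covariates = out.site_covariates.join(joined)
    else:
        out.site_covariates = joined
    return out


def relative_density(detections_count: int, survey_area: float) -> float:
    """Animal detections per square metre of surveyed habitat.

    An index of relative (not absolute) density: visual counts are not
    corrected for imperfect detection.
    """
    if survey_area <= 0:
        raise ValueError("survey_area must be positive (m^2)")
    if detections_count < 0:
        raise ValueError("detections_count must be >= 0")
    return detections_count / survey_area


def aggregate_site_measurements(values: Sequence[float]) -> float:
    """Collapse repeated field measurements at a site to their arithmetic mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or not np.isfinite(arr).all():
        raise ValueError("need at least one finite measurement")
    return float(arr.mean())


def standardize_covariates(dataset: SurveyDataset, names: Iterable[str]) -> SurveyDataset:
    """Scale and center named covariates (mean 0, SD 1, SD with ddof=1).

    The untouched values are kept alongside under ``<name>__raw`` and
    standardization is always recomputed from them, so applying the
    transform twice is exactly the same as applying it once.  The (mean, SD)
    pair is stored in ``dataset.standardization`` for back-transforming
    fitted effects.
    """
    out = dataset.copy()
    for name in names:
        for frame in (out.site_covariates, out.sample_covariates):
            if name in frame.columns:
                raw_col = name + _RAW_SUFFIX
                if raw_col not in frame.columns:
                    frame[raw_col] = frame[name]
                vals = frame[raw_col].to_numpy(float)
                mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
                if not np.isfinite(sd) or sd == 0:
                    raise DegenerateScaleError(f"covariate {name!r} is constant")
                frame[name] = (frame[raw_col] - mean) / sd
                out.standardization[name] = (mean, sd)
                break
        else:
            raise KeyError(f"covariate {name!r} not found")
    return out
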