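"""qPCR detection calling and standard-curve fitting.

A replicate is called positive when its threshold cycle (C_T, the cycle at
which fluorescence crosses the detection threshold) is at or below a cutoff
AND the amplification curve passed visual quality control.  Curve-shape QC
is a human judgement on the instrument's amplification plot, so it enters as
a boolean flag (``curve_ok``) rather than being re-derived from raw
fluorescence.  The default cutoff of 34 cycles corresponds to roughly 80
gene-fragment copies/uL on the assay's serial-dilution standard curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import IntegrityError, SurveyDataset

__all__ = ["QpcrReplicate", "StandardCurve", "call_replicate", "fit_standard_curve",
           "assemble_histories", "DEFAULT_CT_THRESHOLD"]

DEFAULT_CT_THRESHOLD = 34.0


@dataclass(frozen=True)
class QpcrReplicate:
    """One qPCR reaction: C_T (None if no threshold crossing) plus curve QC."""

    ct: float | None = None
    curve_ok: bool = True
    max_cycles: int = 40

    def __post_init__(self) -> None:
        if self.ct is not None and not (0 < self.ct <= self.max_cycles):
            raise ValueError(f"ct must lie in (0, {self.max_cycles}]; got {self.ct}")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of C_T on log10(template concentration)."""

    concentrations: tuple[float, ...]
    ct_values: tuple[float, ...]
    slope: float  # cycles per log10(copies/uL)
    intercept: float  # cycles at 1 copy/uL
    r_squared: float
    efficiency: float  # 1.0 = perfect doubling each cycle

    def predict_ct(self, concentration: float) -> float:
        return self.intercept + self.slope * math.log10(concentration)

    def quantify(self, ct: float) -> float:
        """Concentration (copies/uL) whose expected C_T equals ``ct``."""
        return 10 ** ((ct - self.intercept) / self.slope)


def call_replicate(rep: QpcrReplicate, ct_threshold: float = DEFAULT_CT_THRESHOLD) -> int:
    """Binary detection call: 1 iff C_T present, <= threshold, and curve passed QC.

    Ties at exactly the threshold are positive; only reactions beyond it are
    negated.
    """
    if ct_threshold <= 0:
        raise ValueError("ct_threshold must be positive")
    if rep.ct is None or not rep.curve_ok:
        return 0
    return int(rep.ct <= ct_threshold)


def fit_standard_curve(concentrations, ct_values) -> StandardCurve:
    """Fit the dilution-series calibration line and report amplification efficiency.

    Efficiency is ``10**(-1/slope) - 1``; a slope of -log2(10) = -3.3219
    cycles per tenfold dilution corresponds to perfect efficiency 1.0.
    """
    conc = np.asarray(concentrations, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if conc.size != ct.size:
        raise ValueError("concentrations and ct_values differ in length")
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct concentration points")
    if (conc <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    res = stats.linregress(np.log10(conc), ct)
    slope = float(res.slope)
    return StandardCurve(
        concentrations=tuple(conc),
        ct_values=tuple(ct),
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=10 ** (-1.0 / slope) - 1.0,
    )


def assemble_histories(records, ct_threshold: float = DEFAULT_CT_THRESHOLD) -> SurveyDataset:
    """Turn raw per-replicate qPCR rows into a binary detection dataset.

    ``records`` is an iterable of mappings (or a DataFrame) with columns
    ``site, sample, replicate, ct`` and optionally ``quality_override``
    (truthy = curve failed visual QC, forcing a negative call).  Replicates
    are grouped by (site, sample) in input order; each sample's calls form
    its detection history.
    """
    import pandas as pd

    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    for col in ("site", "sample", "replicate", "ct"):
        if col not in df.columns:
            raise IntegrityError(f"missing column {col!r}")
    override = df["quality_override"] if "quality_override" in df.columns else pd.Series(
        False, index=df.index
    )
    override = override.fillna(False).astype(bool)

    calls = []
    for ct, bad_curve in zip(pd.to_numeric(df["ct"], errors="coerce"), override):
        rep = QpcrReplicate(ct=None if pd.isna(ct) else float(ct), curve_ok=not bad_curve)
        calls.append(call_replicate(rep, ct_threshold))
    long = df.assign(detection=calls)[["site", "sample", "replicate", "detection"]]

    from .data import _records_to_dataset

    return _records_to_dataset(long.astype({"site": str, "sample": str}))
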