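"""Built-in study data: central Texas *Eurycea* salamander eDNA field survey.

The package ships the published summary of a ten-site winter survey of
spring-dwelling (stygophilic/stygobiotic) *Eurycea* salamanders: per-site
visual-encounter counts, surveyed area, and eDNA detection totals (positive
water samples out of samples taken, positive qPCR replicates out of
replicates run; three replicates per 1 L sample).  Nine sites contributed
six water samples; the well site could only hold three.

Per-sample replicate outcomes are reconstructed here in a canonical
arrangement consistent with the per-site totals.  For every model whose
detection probability is constant within a site (all covariates in this
study are site-level), the likelihood depends on the data only through
those totals, so the arrangement is irrelevant to any fit — a property the
test suite asserts rather than assumes.

Also included: the aquarium positive-control detection totals (53 water
samples, each housing a salamander, three qPCR replicates each) and the
visual-encounter-survey histories at the ten field sites, both used for
two-level occupancy fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classic import ClassicHistories
from .data import SurveyDataset, relative_density

__all__ = [
    "FIELD_SITES",
    "field_site_table",
    "field_control_dataset",
    "positive_control_histories",
    "visual_survey_histories",
]

# site, survey area (m^2), visual detections, positive samples, samples,
# positive qPCR replicates, qPCR replicates
FIELD_SITES: list[dict] = [
    {"site": "Avery Deer Spring", "area_m2": 15.0, "salamander_detections": 8,
     "positive_samples": 4, "n_samples": 6, "positive_qpcr": 11, "n_qpcr": 18},
    {"site": "Avery Springhouse Spring", "area_m2": 32.5, "salamander_detections": 16,
     "positive_samples": 2, "n_samples": 6, "positive_qpcr": 6, "n_qpcr": 18},
    {"site": "Brushy Creek Spring", "area_m2": 25.0, "salamander_detections": 0,
     "positive_samples": 2, "n_samples": 6, "positive_qpcr": 6, "n_qpcr": 18},
    {"site": "Cobbs Spring", "area_m2": 28.25, "salamander_detections": 29,
     "positive_samples": 6, "n_samples": 6, "positive_qpcr": 17, "n_qpcr": 18},
    {"site": "Cobbs Well", "area_m2": 0.75, "salamander_detections": 3,
     "positive_samples": 3, "n_samples": 3, "positive_qpcr": 9, "n_qpcr": 9},
    {"site": "Cowan Spring", "area_m2": 10.0, "salamander_detections": 8,
     "positive_samples": 2, "n_samples": 6, "positive_qpcr": 2, "n_qpcr": 18},
    {"site": "Hill Marsh Spring", "area_m2": 58.0, "salamander_detections": 12,
     "positive_samples": 2, "n_samples": 6, "positive_qpcr": 6, "n_qpcr": 18},
    {"site": "PC Spring", "area_m2": 3.0, "salamander_detections": 1,
     "positive_samples": 5, "n_samples": 6, "positive_qpcr": 11, "n_qpcr": 18},
    {"site": "Swinbank Spring", "area_m2": 41.75, "salamander_detections": 60,
     "positive_samples": 5, "n_samples": 6, "positive_qpcr": 14, "n_qpcr": 18},
    {"site": "Twin Springs", "area_m2": 9.0, "salamander_detections": 1,
     "positive_samples": 2, "n_samples": 6, "positive_qpcr": 6, "n_qpcr": 18},
]


def field_site_table() -> pd.DataFrame:
    """Per-site survey summary with salamander relative density (detections/m^2)."""
    df = pd.DataFrame(FIELD_SITES).set_index("site")
    df["density"] = [
        relative_density(r.salamander_detections, r.area_m2) for r in df.itertuples()
    ]
    return df


def _spread_positives(total: int, n_units: int, cap: int) -> list[int]:
    """Split ``total`` positives over ``n_units`` units, each in [1, cap]."""
    assert n_units <= total <= n_units * cap
    counts = []
    remaining, units_left = total, n_units
    for _ in range(n_units):
        units_left -= 1
        take = min(cap, remaining - units_left)  # leave >= 1 for the rest
        counts.append(take)
        remaining -= take
    return counts


def field_control_dataset() -> SurveyDataset:
    """The ten-site field eDNA survey as a three-level :class:`SurveyDataset`.

    Detection histories use the canonical arrangement described in the
    module docstring; the salamander relative-density covariate is attached
    at site level (raw scale — standardize before modelling).
    """
    table = field_site_table()
    site_ids, sample_ids, detections = [], [], []
    for row in table.itertuples():
        site = row.Index
        reps = row.n_qpcr // row.n_samples
        pos_counts = _spread_positives(row.positive_qpcr, row.positive_samples, reps)
        dets, sids = [], []
        for j in range(row.n_samples):
            d = pos_counts[j] if j < len(pos_counts) else 0
            y = np.zeros(reps)
            y[:d] = 1.0
            dets.append(y)
            sids.append(f"S{j + 1}")
        site_ids.append(site)
        sample_ids.append(sids)
        detections.append(dets)
    ds = SurveyDataset(site_ids, sample_ids, detections,
                       site_covariates=table[["density"]].copy())
    return ds


def positive_control_histories() -> ClassicHistories:
    """Aquarium positive control: 53 salamander-housing samples, 3 qPCR each.

    eDNA was detected in 52 of 53 samples and 153 of 159 replicates.  The
    published account does not give the per-sample split of the six
    negative replicates; the two-level likelihood depends only on the
    totals (one all-negative sample; 153 positives among the 156 replicates
    of the remaining 52), so any arrangement gives the identical fit.
    """
    detections = np.array([0] + [3] * 49 + [2] * 3)
    trials = np.full(53, 3)
    return ClassicHistories(detections, trials)


def visual_survey_histories() -> ClassicHistories:
    """Visual encounter surveys at the ten field sites (2-4 visits per site).

    Salamanders were seen on every visit at eight sites (24 surveys in
    total), on two of four visits at Twin Springs, and on neither of two
    visits at Brushy Creek Spring: 26 detections in 30 surveys.
    """
    detections = np.array([3] * 8 + [2, 0])
    trials = np.array([3] * 8 + [4, 2])
    return ClassicHistories(detections, trials)
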