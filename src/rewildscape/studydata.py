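"""Reference values from the published Cilento rewilding survey.

These are the printed results of the field study this pipeline
re-implements at desk scale — a camera-trap survey of roe deer
(*Capreolus capreolus italicus*) and red deer (*Cervus elaphus*)
reintroduced to the Cilento region of the Southern Apennines.  They are
bundled as worked-example INPUTS (the raw detections, presence points and
demographic parameter files were not deposited): the package recomputes
the derived quantities from them, it does not re-estimate them.
"""

from __future__ import annotations

#: Per-cell REM densities (ind/km^2) for red deer, one value per surveyed
#: 2 x 2 km cell (cells A-N).  Their unweighted mean is the study-area
#: density reported for the species.
RED_DEER_CELL_DENSITIES: list[float] = [
    3.56, 0.51, 0.59, 0.86, 0.42, 0.00, 0.27, 0.00, 0.00, 0.22, 0.00, 0.00,
]

#: Roe deer per-cell densities (same cells, for reference).
ROE_DEER_CELL_DENSITIES: list[float] = [
    6.01, 2.60, 1.32, 2.48, 2.11, 0.00, 1.17, 0.00, 0.00, 2.25, 0.55, 0.00,
]

#: Livestock per-cell densities.
LIVESTOCK_CELL_DENSITIES: list[float] = [
    4.14, 0.62, 1.69, 3.72, 0.00, 0.20, 0.25, 0.00, 0.20, 2.57, 0.36, 0.67,
]

#: Habitat-suitability extents (km^2) by level, per species.
SUITABILITY_AREAS_KM2: dict[str, dict[str, float]] = {
    "roe_deer": {"medium": 454.0, "high": 233.0},
    "red_deer": {"medium": 238.0, "high": 642.0},
}

#: Suitability thresholds: 10th-percentile training presence and maxSSS.
THRESHOLDS: dict[str, dict[str, float]] = {
    "roe_deer": {"p10": 0.221, "maxsss": 0.559},
    "red_deer": {"p10": 0.209, "maxsss": 0.621},
}

#: Succession areas (km^2) split by suitable habitat for the deer:
#: inside / outside the suitable range.
SUCCESSION_AREAS_KM2: dict[str, dict[str, float]] = {
    "IS": {"inside": 11.71, "outside": 14.59},
    "SS": {"inside": 4.33, "outside": 27.93},
}

#: PVA population sizes ~19 years after release (mean over iterations).
PVA_POPULATION: dict[str, float] = {"roe_deer": 175.61, "red_deer": 84.28}

#: Individuals released 2003-2006.
RELEASED: dict[str, int] = {"roe_deer": 37, "red_deer": 35}
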