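"""Ecosystem-function proxies: orientation, normalisation, and averaged /
multi-threshold multifunctionality.

Thirteen proxies spanning water regulation, organic-matter decomposition,
nutrient cycling, mutualism, plant-pathogen control and antibiotic-
resistance-gene (ARG) control are treated as benefits.  Two of them
(fungal plant pathogen abundance, ARG abundance) arrive on an inverted-
benefit scale (higher = worse) and are multiplied by -1 before
normalisation.  Averaged multifunctionality is the per-sample mean of
the 0-1 normalised, benefit-oriented proxies.  Threshold
multifunctionality MF_t counts, per sample, the functions whose value
exceeds a fixed proportion t of that function's maximum observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from chronobef.community import minmax_normalize

#: default function names; the last two are emitted as inverted benefits
DEFAULT_FUNCTIONS = (
    "potential_infiltration",
    "water_holding_capacity",
    "soil_respiration",
    "lignin_degradation",
    "chitin_degradation",
    "sugar_degradation",
    "p_mineralization",
    "available_n",
    "available_p",
    "emf_abundance",
    "amf_abundance",
    "fungal_plant_pathogens",
    "args_abundance",
)

#: functions whose raw scale is "higher = worse"
DEFAULT_INVERTED = ("fungal_plant_pathogens", "args_abundance")

#: service category per function (reporting only)
SERVICE_CATEGORIES = {
    "potential_infiltration": "water regulation",
    "water_holding_capacity": "water regulation",
    "soil_respiration": "decomposition",
    "lignin_degradation": "decomposition",
    "chitin_degradation": "decomposition",
    "sugar_degradation": "decomposition",
    "p_mineralization": "decomposition",
    "available_n": "nutrient cycling",
    "available_p": "nutrient cycling",
    "emf_abundance": "mutualism",
    "amf_abundance": "mutualism",
    "fungal_plant_pathogens": "pathogen control",
    "args_abundance": "ARG control",
}


@dataclass
class FunctionMatrix:
    """Function proxies, functions (rows) x samples (columns).

    ``orientation`` maps each function name to ``"benefit"`` or
    ``"invert"``; flagged rows are multiplied by -1 by :func:`orient`
    before 0-1 normalisation.
    """

    values: pd.DataFrame
    orientation: dict[str, str]
    oriented: bool = field(default=False)
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        for name, flag in self.orientation.items():
            if flag not in ("benefit", "invert"):
                raise ValueError(
                    f"unknown orientation flag {flag!r} for function {name!r}"
                )
        missing = set(self.values.index) - set(self.orientation)
        if missing:
            raise ValueError(f"orientation flags missing for {sorted(missing)}")

    @property
    def function_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ThresholdSpec:
    """Thresholds for MF_t, as proportions of the per-function maximum
    observed value.

    ``comparison`` is ``"strict"`` (count f > t, the printed form of the
    index) or ``"ge"`` (count f >= t).
    """

    thresholds: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 0.90)
    comparison: str = "strict"
    reference: str = "max"  # or "robust_max" (mean of top-k values)
    robust_k: int = 3

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if len(ts) == 0:
            raise ValueError("threshold list must be non-empty")
        if any(not (0.0 < t < 1.0) for t in ts):
            raise ValueError(f"thresholds must lie in (0, 1): {ts}")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {ts}")
        if self.comparison not in ("strict", "ge"):
            raise ValueError(f"comparison must be 'strict' or 'ge', got {self.comparison!r}")
        if self.reference not in ("max", "robust_max"):
            raise ValueError(f"reference must be 'max' or 'robust_max', got {self.reference!r}")
        self.thresholds = ts


def orient(matrix: FunctionMatrix) -> FunctionMatrix:
    """Multiply inverted-benefit rows by -1; benefit rows pass through.

    Applying :func:`orient` twice returns the original values (the flags
    are not consumed), so the operation is an involution.
    """
    vals = matrix.values.copy()
    for name in vals.index:
        if matrix.orientation[name] == "invert":
            vals.loc[name] = -vals.loc[name]
    return replace(matrix, values=vals, oriented=not matrix.oriented)


def normalize(matrix: FunctionMatrix) -> FunctionMatrix:
    """0-1 normalise each (oriented) function across all samples."""
    if not matrix.oriented:
        raise ValueError("normalize expects an oriented matrix; call orient() first")
    vals = matrix.values.copy()
    for name in vals.index:
        row = vals.loc[name]
        if row.isna().all():
            raise ValueError(f"function {name!r} has no observed values")
        vals.loc[name] = minmax_normalize(row.astype(float))
    return replace(matrix, values=vals, normalized=True)


def average_mf(matrix: FunctionMatrix) -> pd.Series:
    """Averaged multifunctionality: per-sample mean of the normalised,
    benefit-oriented functions.  Lies in [0, 1]."""
    if not (matrix.oriented and matrix.normalized):
        raise ValueError("average_mf expects an oriented, normalised matrix")
    mf = matrix.values.mean(axis=0)
    mf.name = "MF_avg"
    return mf


def threshold_mf(matrix: FunctionMatrix, spec: ThresholdSpec | None = None) -> pd.DataFrame:
    """Multi-threshold multifunctionality.

    MF_t(sample) = number of functions whose value exceeds
    t x (per-function reference maximum).  On the normalised scale the
    reference maximum is 1, so the cut point is the threshold itself;
    on a raw oriented scale the reference is the per-function maximum
    observed value (or a top-k mean if ``spec.reference == "robust_max"``).

    Returns a samples x thresholds integer DataFrame with columns
    ``MF_t10`` etc.  MF_t is nonincreasing in t for every sample.
    """
    if spec is None:
        spec = ThresholdSpec()
    if not matrix.oriented:
        raise ValueError("threshold_mf expects an oriented matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if spec.reference == "max":
        ref = np.nanmax(vals, axis=1)
    else:
        k = min(spec.robust_k, vals.shape[1])
        ref = np.sort(vals, axis=1)[:, -k:].mean(axis=1)
    out = {}
    for t in spec.thresholds:
        cuts = t * ref
        if spec.comparison == "strict":
            hits = vals > cuts[:, None]
        else:
            hits = vals >= cuts[:, None]
        out[f"MF_t{int(round(t * 100))}"] = hits.sum(axis=0)
    return pd.DataFrame(out, index=matrix.values.columns).astype(int)


def multifunctionality_table(
    raw: FunctionMatrix, spec: ThresholdSpec | None = None
) -> pd.DataFrame:
    """Orient, normalise, and compute MF_avg plus all threshold MF columns.

    Thresholds are applied on the normalised scale, anchored at each
    function's maximum observed value as the reference.
    """
    oriented = orient(raw) if not raw.oriented else raw
    norm = normalize(oriented) if not oriented.normalized else oriented
    out = pd.DataFrame({"MF_avg": average_mf(norm)})
    out = out.join(threshold_mf(norm, spec))
    out.index.name = "sample_id"
    return out
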