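"""Otolith back-calculation of length-at-age by the biological intercept.

The biological intercept method (a proportional body-otolith growth model
anchored at a known size at hatch) maps each annulus radius Oa to the length
the fish had when that annulus formed:

    La = Lc + (Oa - Oc) * (Lc - L0) / (Oc - O0)

with Lc/Oc the length and otolith radius at capture and (L0, O0) the
biological intercept.  Arctic char hatch at about 17 mm, which fixes L0; the
hatch radius O0 is estimated from the youngest fish by extrapolating their
log-linear annual-increment-versus-age relationship back to the first year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HATCH_LENGTH_MM = 17.0

__all__ = [
    "HATCH_LENGTH_MM",
    "OtolithRecord",
    "GrowthCurve",
    "estimate_biological_intercept",
    "back_calculate",
    "growth_summary",
    "otoliths_to_frame",
    "frame_to_otoliths",
]


@dataclass
class OtolithRecord:
    fish_id: str
    capture_length: float  # mm
    capture_radius: float  # otolith units
    annulus_radii: np.ndarray  # strictly increasing, one per age
    hatch_length: float = HATCH_LENGTH_MM

    def __post_init__(self) -> None:
        self.annulus_radii = np.asarray(self.annulus_radii, dtype=float)
        if len(self.annulus_radii) < 1:
            raise ValueError("need at least one annulus")
        if np.any(np.diff(self.annulus_radii) <= 0):
            raise ValueError("annulus radii must be strictly increasing")
        if self.annulus_radii[-1] > self.capture_radius + 1e-12:
            raise ValueError("annulus radius exceeds capture radius")

    @property
    def age(self) -> int:
        return len(self.annulus_radii)


@dataclass
class GrowthCurve:
    """Per-group, per-age mean and sd of back-calculated length."""

    table: pd.DataFrame  # columns: group, age, mean_mm, sd_mm, n


def estimate_biological_intercept(
    records: list[OtolithRecord], n_youngest: int = 5
) -> tuple[float, float, pd.DataFrame]:
    """Estimate the biological intercept (L0, O0) from the youngest fish.

    L0 is fixed at the 17 mm hatch length.  For each of the ``n_youngest``
    youngest fish (minimum age 3, so at least two increments are observable
    without knowing O0), the log10 annual otolith increment is regressed on
    age over ages >= 2 and extrapolated to age 1; the hatch radius is then
    O1 minus the predicted first-year increment, averaged over fish.
    Returns (L0, O0, diagnostics table).
    """
    eligible = [r for r in records if r.age >= 3]
    if len(eligible) < n_youngest:
        raise ValueError(
            f"need at least {n_youngest} records of age >= 3, have {len(eligible)}"
        )
    eligible.sort(key=lambda r: (r.age, r.fish_id))
    chosen = eligible[:n_youngest]
    rows = []
    o0_estimates = []
    for rec in chosen:
        radii = rec.annulus_radii
        incr = np.diff(radii)  # increments for ages 2..age
        ages = np.arange(2, rec.age + 1, dtype=float)
        if np.any(incr <= 0):
            raise ValueError(f"nonpositive increment for fish {rec.fish_id}")
        y = np.log10(incr)
        if len(ages) >= 2 and np.ptp(ages) > 0:
            slope, intercept = np.polyfit(ages, y, 1)
        else:
            slope, intercept = 0.0, y[0]
        pred_first = 10.0 ** (intercept + slope * 1.0)
        o0 = radii[0] - pred_first
        o0_estimates.append(o0)
        rows.append(
            {
                "fish_id": rec.fish_id,
                "age": rec.age,
                "slope": slope,
                "intercept": intercept,
                "o0": o0,
            }
        )
    o0_mean = float(np.mean(o0_estimates))
    if o0_mean < 0:
        o0_mean = 0.0
    return HATCH_LENGTH_MM, o0_mean, pd.DataFrame(rows)


def back_calculate(record: OtolithRecord, L0: float, O0: float) -> np.ndarray:
    """Length at each annulus age by the biological intercept formula."""
    if record.capture_radius <= O0:
        raise ValueError("capture radius must exceed the hatch radius O0")
    Lc, Oc = record.capture_length, record.capture_radius
    La = Lc + (record.annulus_radii - Oc) * (Lc - L0) / (Oc - O0)
    if np.any(La <= 0):
        import warnings

        warnings.warn(f"nonpositive back-calculated length for fish {record.fish_id}")
    return La


def growth_summary(
    curves: dict[str, np.ndarray], grouping: dict[str, str]
) -> GrowthCurve:
    """Per-group per-age mean +/- sd (sd missing with n = 1) of length-at-age.

    ``curves`` maps fish id to its back-calculated length vector (index a-1
    holds length at age a); ``grouping`` maps fish id to a group label.
    """
    groups = sorted(set(grouping.values()))
    rows = []
    for grp in groups:
        members = [fid for fid, g in grouping.items() if g == grp and fid in curves]
        if not members:
            raise ValueError(f"group {grp} has no fish with growth curves")
        max_age = max(len(curves[f]) for f in members)
        for age in range(1, max_age + 1):
            vals = np.array(
                [curves[f][age - 1] for f in members if len(curves[f]) >= age]
            )
            rows.append(
                {
                    "group": grp,
                    "age": age,
                    "mean_mm": float(vals.mean()),
                    "sd_mm": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                }
            )
    return GrowthCurve(table=pd.DataFrame(rows))


def otoliths_to_frame(records: list[OtolithRecord]) -> pd.DataFrame:
    """Tidy TSV-ready form: one row per (fish, annulus)."""
    rows = []
    for r in records:
        for a, radius in enumerate(r.annulus_radii, start=1):
            rows.append(
                {
                    "fish_id": r.fish_id,
                    "age_index": a,
                    "radius": radius,
                    "capture_radius": r.capture_radius,
                    "capture_length_mm": r.capture_length,
                }
            )
    return pd.DataFrame(rows)


def frame_to_otoliths(df: pd.DataFrame) -> list[OtolithRecord]:
    records = []
    for fid, sub in df.groupby("fish_id", sort=False):
        sub = sub.sort_values("age_index")
        records.append(
            OtolithRecord(
                fish_id=str(fid),
                capture_length=float(sub["capture_length_mm"].iloc[0]),
                capture_radius=float(sub["capture_radius"].iloc[0]),
                annulus_radii=sub["radius"].to_numpy(dtype=float),
            )
        )
    return records
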