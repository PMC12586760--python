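"""Growth-curve parameterization for little penguin chicks.

Chicks are weighed every few days from the end of the guard phase (the
first time parents leave them alone by day) until fledging.  This module
turns those longitudinal mass series into eleven descriptors of the
growth curve, grouped by what they measure:

* magnitude — peak mass, fledging mass, relative post-peak mass loss,
  and the signed relative mass difference to the sibling chick;
* rate — guard duration (age at first weighing), the steepest sustained
  linear growth segment (slope, onset, duration), age at peak mass and
  age at fledging;
* form — an irregularity index: the mean absolute deviation of observed
  masses from a loess-smoothed version of the curve.

Only chicks weighed at least five times are analyzable; the rest are
excluded and reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_MEASUREMENTS = 5
#: fledging is operationalized as leaving the nest after this age ...
FLEDGE_MIN_AGE_DAYS = 45
#: ... having reached at least this peak mass
FLEDGE_MIN_PEAK_G = 800.0

PARAM_COLUMNS = [
    "peak_mass",
    "fledge_mass",
    "rel_mass_loss",
    "sibling_delta",
    "guard_duration",
    "steepest_slope",
    "steepest_slope_duration",
    "steepest_slope_start",
    "age_at_peak",
    "age_at_fledge",
    "irregularity",
]

#: the seven weakly correlated parameters retained for PCA/clustering
CLUSTERING_COLUMNS = [
    "peak_mass",
    "rel_mass_loss",
    "sibling_delta",
    "guard_duration",
    "steepest_slope",
    "age_at_peak",
    "irregularity",
]


@dataclass
class MassSeries:
    """One chick's longitudinal (age, mass) measurements.

    Ages are integer-precision days post-hatching (hatching = day 0);
    masses are grams.  Ages must be strictly increasing and masses
    positive.  A series is *analyzable* when it has at least
    :data:`MIN_MEASUREMENTS` measurements.
    """

    chick_id: str
    brood_id: str
    season: int
    ages: np.ndarray
    masses: np.ndarray
    fledged: bool = False

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.ages.shape != self.masses.shape or self.ages.ndim != 1:
            raise ValueError("ages and masses must be 1-D arrays of equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(f"ages must be strictly increasing (chick {self.chick_id})")
        if np.any(self.masses <= 0):
            raise ValueError(f"masses must be positive (chick {self.chick_id})")

    @property
    def n(self) -> int:
        return len(self.ages)

    @property
    def analyzable(self) -> bool:
        return self.n >= MIN_MEASUREMENTS


@dataclass
class SmoothFit:
    """Loess fit evaluated at the observed ages; fitted + residuals == observed."""

    fitted: np.ndarray
    residuals: np.ndarray
    span: float
    degree: int


@dataclass
class GrowthParams:
    """The eleven growth-curve descriptors of one chick."""

    chick_id: str
    peak_mass: float
    fledge_mass: float
    rel_mass_loss: float
    sibling_delta: float | None
    guard_duration: float
    steepest_slope: float
    steepest_slope_duration: float
    steepest_slope_start: float
    age_at_peak: float
    age_at_fledge: float
    irregularity: float
    fledged: bool = False

    def as_dict(self) -> dict:
        d = {c: getattr(self, c) for c in PARAM_COLUMNS}
        d["chick_id"] = self.chick_id
        d["fledged"] = self.fledged
        if d["sibling_delta"] is None:
            d["sibling_delta"] = np.nan
        return d


@dataclass
class ValidationReport:
    n_input_rows: int = 0
    n_rejected_rows: int = 0
    rejected_reasons: list = field(default_factory=list)
    excluded_chicks: list = field(default_factory=list)  # (chick_id, n_measurements)
    n_series: int = 0


def validate_series(raw: pd.DataFrame) -> tuple[list[MassSeries], ValidationReport]:
    """Build per-chick :class:`MassSeries` from a raw measurement table.

    ``raw`` needs columns ``chick_id, brood_id, season, age_days, mass_g``.
    Rows with non-positive mass or negative age are rejected (and logged);
    duplicate-age rows for one chick are averaged; chicks with fewer than
    five remaining measurements are excluded and listed in the report.
    """
    required = {"chick_id", "brood_id", "season", "age_days", "mass_g"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")

    report = ValidationReport(n_input_rows=len(raw))
    bad = (raw["mass_g"] <= 0) | (raw["age_days"] < 0)
    for _, row in raw[bad].iterrows():
        reason = "non-positive mass" if row["mass_g"] <= 0 else "negative age"
        report.rejected_reasons.append((row["chick_id"], float(row["age_days"]), reason))
        logger.warning("rejected row chick=%s age=%s: %s", row["chick_id"], row["age_days"], reason)
    report.n_rejected_rows = int(bad.sum())
    clean = raw[~bad]

    series: list[MassSeries] = []
    for chick_id, grp in clean.groupby("chick_id", sort=True):
        agg = grp.groupby("age_days", as_index=False)["mass_g"].mean().sort_values("age_days")
        if len(agg) < MIN_MEASUREMENTS:
            report.excluded_chicks.append((chick_id, len(agg)))
            continue
        ages = agg["age_days"].to_numpy(dtype=float)
        masses = agg["mass_g"].to_numpy(dtype=float)
        fledged = bool(ages[-1] > FLEDGE_MIN_AGE_DAYS and masses.max() >= FLEDGE_MIN_PEAK_G)
        series.append(
            MassSeries(
                chick_id=str(chick_id),
                brood_id=str(grp["brood_id"].iloc[0]),
                season=int(grp["season"].iloc[0]),
                ages=ages,
                masses=masses,
                fledged=fledged,
            )
        )
    report.n_series = len(series)
    return series, report


def _loess_point(x: np.ndarray, y: np.ndarray, x0: float, q: int, degree: int) -> float:
    """Tricube-weighted polynomial fit around x0, evaluated at x0."""
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    dmax = d[idx].max()
    if dmax == 0:
        return float(np.mean(y[idx]))
    w = (1.0 - np.clip(d[idx] / dmax, 0.0, 1.0) ** 3) ** 3
    xw, yw = x[idx], y[idx]
    # weighted least squares on a local polynomial, centred for conditioning
    X = np.vander(xw - x0, degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
    return float(beta[0])


def loess_smooth(series: MassSeries, span: float = 0.9, degree: int = 2) -> SmoothFit:
    """Local polynomial (loess) regression of mass on age.

    Uses tricube weights over a nearest-neighbour window of
    ``ceil(span * n)`` points and no robustness iterations, evaluated at
    each observed age.
    """
    if not series.analyzable:
        raise ValueError(f"series {series.chick_id} has {series.n} < {MIN_MEASUREMENTS} measurements")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = series.n
    q = math.ceil(span * n)
    if q < degree + 2:
        raise ValueError(
            f"loess window of {q} points cannot support a degree-{degree} local fit; "
            f"need at least {degree + 2} points per window"
        )
    fitted = np.array(
        [_loess_point(series.ages, series.masses, a, q, degree) for a in series.ages]
    )
    return SmoothFit(fitted=fitted, residuals=series.masses - fitted, span=span, degree=degree)


def irregularity_index(series: MassSeries, span: float = 0.9) -> float:
    """Mean absolute deviation of observed masses from their loess smooth (grams)."""
    fit = loess_smooth(series, span=span, degree=2)
    return float(np.mean(np.abs(fit.residuals)))


def steepest_slope_segment(
    series: MassSeries, min_points: int = 3, min_span_days: float = 5.0
) -> tuple[float, float, float]:
    """Steepest sustained linear growth segment.

    Searches every contiguous window of measurements with at least
    ``min_points`` points spanning at least ``min_span_days`` days, fits
    ordinary least squares mass ~ age per window, and returns the window
    of maximum slope as ``(slope g/day, start age, duration days)``.
    Slope ties resolve toward the longer, then the earlier, window.
    """
    if not series.analyzable:
        raise ValueError(f"series {series.chick_id} has {series.n} < {MIN_MEASUREMENTS} measurements")
    x, y = series.ages, series.masses
    n = series.n
    best: tuple[float, float, float] | None = None
    for i in range(n):
        for j in range(i + min_points - 1, n):
            dur = x[j] - x[i]
            if dur < min_span_days:
                continue
            xs = x[i : j + 1]
            ys = y[i : j + 1]
            xc = xs - xs.mean()
            slope = float(np.dot(xc, ys) / np.dot(xc, xc))
            if best is None:
                best = (slope, float(x[i]), float(dur))
                continue
            tol = 1e-9 * max(1.0, abs(best[0]))
            if slope > best[0] + tol:
                best = (slope, float(x[i]), float(dur))
            elif abs(slope - best[0]) <= tol:
                if dur > best[2] + 1e-12 or (abs(dur - best[2]) <= 1e-12 and x[i] < best[1]):
                    best = (slope, float(x[i]), float(dur))
    if best is None:
        raise ValueError(
            f"no window with >= {min_points} points spanning >= {min_span_days} days "
            f"in series {series.chick_id}"
        )
    return best


def sibling_delta(focal: MassSeries, sibling: MassSeries | None) -> float | None:
    """Signed relative mass difference to the sibling, from the focal chick's side.

    At each shared measurement age i the relative difference is
    ``(m_focal,i - m_sib,i) / mean(m_focal,i, m_sib,i)``; the delta is the
    mean over the N shared ages.  Returns ``None`` when there is no
    sibling or no shared age (missing; imputed downstream).
    """
    if sibling is None:
        return None
    shared, ia, ib = np.intersect1d(focal.ages, sibling.ages, return_indices=True)
    if len(shared) == 0:
        return None
    ma, mb = focal.masses[ia], sibling.masses[ib]
    return float(np.mean((ma - mb) / ((ma + mb) / 2.0)))


def compute_growth_params(
    series: MassSeries,
    sibling: MassSeries | None = None,
    span: float = 0.9,
    min_points: int = 3,
    min_span_days: float = 5.0,
) -> GrowthParams:
    """All eleven growth descriptors for one chick.

    Peak mass ties resolve to the earliest age (mass recession follows
    the peak, so the first maximum is the biological peak).  Guard
    duration is read off the age of the first measurement, since weighing
    starts when the guard phase ends.
    """
    if not series.analyzable:
        raise ValueError(f"series {series.chick_id} has {series.n} < {MIN_MEASUREMENTS} measurements")
    i_peak = int(np.argmax(series.masses))  # argmax takes the first maximum
    peak = float(series.masses[i_peak])
    last = float(series.masses[-1])
    slope, start, duration = steepest_slope_segment(series, min_points, min_span_days)
    return GrowthParams(
        chick_id=series.chick_id,
        peak_mass=peak,
        fledge_mass=last,
        rel_mass_loss=(peak - last) / peak,
        sibling_delta=sibling_delta(series, sibling),
        guard_duration=float(series.ages[0]),
        steepest_slope=slope,
        steepest_slope_duration=duration,
        steepest_slope_start=start,
        age_at_peak=float(series.ages[i_peak]),
        age_at_fledge=float(series.ages[-1]),
        irregularity=irregularity_index(series, span=span),
        fledged=series.fledged,
    )


def params_table(
    series: list[MassSeries],
    broods: pd.DataFrame | None = None,
    span: float = 0.9,
    min_points: int = 3,
    min_span_days: float = 5.0,
) -> pd.DataFrame:
    """Growth-parameter table, one row per analyzable chick.

    ``broods`` (columns ``brood_id, chick_id``) supplies sibling pairing;
    without it, siblings are matched on the ``brood_id`` carried by the
    series themselves.
    """
    by_id = {s.chick_id: s for s in series}
    brood_of: dict[str, str] = {}
    if broods is not None:
        for _, row in broods.iterrows():
            brood_of[str(row["chick_id"])] = str(row["brood_id"])
    else:
        brood_of = {s.chick_id: s.brood_id for s in series}
    members: dict[str, list[str]] = {}
    for cid, bid in brood_of.items():
        members.setdefault(bid, []).append(cid)

    rows = []
    for s in series:
        sib = None
        mates = [c for c in members.get(brood_of.get(s.chick_id, s.brood_id), []) if c != s.chick_id]
        if len(mates) > 1:
            raise ValueError(f"brood {s.brood_id} has more than two chicks")
        if mates and mates[0] in by_id:
            sib = by_id[mates[0]]
        rows.append(compute_growth_params(s, sib, span, min_points, min_span_days).as_dict())
    df = pd.DataFrame(rows).set_index("chick_id")
    return df[PARAM_COLUMNS + ["fledged"]]


def brood_cross_tab(assignments: dict[str, str], broods: pd.DataFrame) -> pd.DataFrame:
    """Contingency of the sibling's cluster (rows) by the focal chick's cluster.

    Rows are ``none`` (no sibling) plus the cluster labels; columns are
    the focal chick's cluster.  Column proportions are appended as a
    second level.  Broods with more than two chicks are an error.
    """
    members: dict[str, list[str]] = {}
    for _, row in broods.iterrows():
        members.setdefault(str(row["brood_id"]), []).append(str(row["chick_id"]))
    for bid, cids in members.items():
        if len(cids) > 2:
            raise ValueError(f"brood {bid} has {len(cids)} chicks; at most 2 expected")
    sib_of: dict[str, str | None] = {}
    for cids in members.values():
        if len(cids) == 1:
            sib_of[cids[0]] = None
        else:
            a, b = cids
            sib_of[a], sib_of[b] = b, a

    labels = sorted(set(assignments.values()))
    rows = ["none"] + labels
    table = pd.DataFrame(0, index=rows, columns=labels, dtype=int)
    for chick, lab in assignments.items():
        sib = sib_of.get(chick)
        sib_lab = assignments.get(sib) if sib is not None else None
        table.loc[sib_lab if sib_lab is not None else "none", lab] += 1
    props = table / table.sum(axis=0).replace(0, np.nan)
    props.index = [f"{r} (prop)" for r in props.index]
    return pd.concat([table, props.round(4)])
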