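"""Cooperativity estimation from quantified gel lanes.

An electrophoretic mobility shift assay (EMSA) lane resolves the four
occupancy microstates of a composite probe into four bands.  After
quantifying band intensities, the cooperativity factor is the plug-in
statistic

    omega = (f_dimer * f_free) / (f_sox * f_pax)

a ratio of ratios that cancels the unknown equilibrium free concentrations:
for fractions generated by the four-microstate equilibrium model, the
statistic recovers the model's omega exactly, whatever the totals.
omega > 1 indicates cooperative binding, omega = 1 additive (independent)
binding, and omega < 1 competition; log2(omega) < 0 is how "negative
cooperativity" is encoded, since a ratio of non-negative fractions cannot
itself be negative.

Estimates from lanes whose monomer or ternary bands fall below a
detectability threshold are flagged unreliable rather than discarded
silently — faint-band lanes are the regime where the statistic blows up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .equilibrium import MicrostateFractions

__all__ = [
    "LaneQuantification",
    "CooperativityEstimate",
    "ReplicateSummary",
    "KdFit",
    "LaneError",
    "SummaryError",
    "FitError",
    "DEFAULT_EPSILON",
    "normalize_lane",
    "estimate_omega",
    "summarize_replicates",
    "fit_kd",
    "read_lane_table",
    "estimates_frame",
]

#: Default detectability threshold: a band below 1% of total lane signal is
#: treated as not reliably quantifiable.
DEFAULT_EPSILON = 0.01


class LaneError(ValueError):
    pass


class SummaryError(ValueError):
    def __init__(self, message: str, reasons: list[str] | None = None):
        super().__init__(message)
        self.reasons = reasons or []


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class LaneQuantification:
    """Raw band intensities of one gel lane (arbitrary units, >= 0)."""

    lane_id: str
    i_free: float
    i_sox: float
    i_pax: float
    i_dimer: float

    def __post_init__(self) -> None:
        for name in ("i_free", "i_sox", "i_pax", "i_dimer"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise LaneError(f"lane {self.lane_id}: {name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.i_free + self.i_sox + self.i_pax + self.i_dimer


@dataclass(frozen=True)
class CooperativityEstimate:
    """One lane's cooperativity estimate with a reliability verdict.

    ``omega`` is ``math.inf`` when a denominator band is exactly zero at
    epsilon 0 — flagged, never raised.  ``reliable`` is False whenever any
    band entering the statistic is below the detectability threshold;
    ``unreliable_reason`` says which.
    """

    omega: float
    log2_omega: float
    reliable: bool
    unreliable_reason: str = ""

    def __post_init__(self) -> None:
        if not (self.omega >= 0 or math.isnan(self.omega)):
            raise LaneError(f"omega must be >= 0, got {self.omega!r}")


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate statistics of omega over the reliable lanes only.

    Median and interquartile range are the primary summary (boxplot
    convention); mean and standard deviation accompany them for barplot-style
    reporting.
    """

    n: int
    median: float
    iqr_low: float
    iqr_high: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SummaryError("replicate summary requires n >= 1")
        if not (self.iqr_low <= self.median <= self.iqr_high):
            raise SummaryError("IQR must bracket the median")


@dataclass(frozen=True)
class KdFit:
    """Result of a single-site dissociation-constant fit."""

    kd_hat: float
    residual_norm: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.kd_hat > 0:
            raise FitError(f"kd_hat must be > 0, got {self.kd_hat!r}")


def normalize_lane(lane: LaneQuantification) -> MicrostateFractions:
    """Convert raw band intensities to microstate fractions (sum to 1)."""
    total = lane.total
    if total <= 0:
        raise LaneError(f"lane {lane.lane_id}: all band intensities are zero")
    return MicrostateFractions(
        lane.i_free / total, lane.i_sox / total, lane.i_pax / total, lane.i_dimer / total
    )


def estimate_omega(
    fr: MicrostateFractions, epsilon: float = DEFAULT_EPSILON
) -> CooperativityEstimate:
    """Compute the cooperativity statistic from one lane's fractions.

    Lanes whose monomer bands (f_sox, f_pax) or ternary band (f_dimer) fall
    below ``epsilon`` are flagged unreliable; omega is still reported where
    it is finite.  A zero denominator with epsilon=0 yields an infinite,
    flagged estimate rather than an exception.
    """
    reasons = []
    if fr.f_sox < epsilon or fr.f_pax < epsilon:
        reasons.append("monomer band below detectability")
    if fr.f_dimer < epsilon:
        reasons.append("ternary band barely detectable")

    denom = fr.f_sox * fr.f_pax
    numer = fr.f_dimer * fr.f_free
    if denom > 0:
        omega = numer / denom
    elif numer > 0:
        omega = math.inf
        if not reasons:
            reasons.append("monomer band below detectability")
    else:
        omega = math.nan
        if not reasons:
            reasons.append("statistic undefined: 0/0")

    log2_omega = math.log2(omega) if (omega > 0 and math.isfinite(omega)) else (
        math.inf if omega == math.inf else -math.inf if omega == 0 else math.nan
    )
    return CooperativityEstimate(
        omega=omega,
        log2_omega=log2_omega,
        reliable=not reasons,
        unreliable_reason="; ".join(reasons),
    )


def summarize_replicates(estimates: list[CooperativityEstimate]) -> ReplicateSummary:
    """Summarize omega over the reliable replicates (median/IQR + mean/sd)."""
    reliable = [e.omega for e in estimates if e.reliable]
    if not reliable:
        raise SummaryError(
            "no reliable replicate estimates",
            reasons=[e.unreliable_reason for e in estimates if not e.reliable],
        )
    arr = np.asarray(reliable, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return ReplicateSummary(
        n=len(arr),
        median=float(med),
        iqr_low=float(q1),
        iqr_high=float(q3),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def fit_kd(titration: list[tuple[float, float]]) -> KdFit:
    """Least-squares fit of a single-site isotherm bound = P / (P + Kd).

    ``titration`` is a list of (protein total nM, bound fraction) pairs; the
    probe is assumed to be in trace amounts so the protein total stands in
    for its free concentration.  Requires >= 3 points with distinct protein
    totals and non-degenerate bound fractions.
    """
    if len(titration) < 3:
        raise FitError(f"need >= 3 titration points, got {len(titration)}")
    conc = np.asarray([p for p, _ in titration], dtype=float)
    bound = np.asarray([b for _, b in titration], dtype=float)
    if len(set(conc.tolist())) != len(conc):
        raise FitError("protein totals must be distinct")
    if np.all(bound <= 0) or np.all(bound >= 1):
        raise FitError("degenerate titration: all points unbound or all saturated")

    def resid(log_kd):
        return bound - conc / (conc + np.exp(log_kd))

    # half-saturation concentration as a scale-free starting point
    x0 = math.log(max(np.median(conc), 1e-6))
    sol = least_squares(resid, x0=[x0], method="lm", xtol=1e-15, ftol=1e-15)
    kd_hat = float(np.exp(sol.x[0]))
    return KdFit(kd_hat=kd_hat, residual_norm=float(np.linalg.norm(sol.fun)), n_points=len(conc))


LANE_COLUMNS = ["lane_id", "element", "replicate", "i_free", "i_sox", "i_pax", "i_dimer"]


def read_lane_table(path) -> pd.DataFrame:
    """Read a TSV of quantified lanes (header required, columns LANE_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LANE_COLUMNS if c not in df.columns]
    if missing:
        raise LaneError(f"lane table missing columns: {missing}")
    return df


def estimates_frame(df: pd.DataFrame, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Per-lane omega estimates for a lane table, as a tidy DataFrame."""
    rows = []
    for _, row in df.iterrows():
        lane = LaneQuantification(
            lane_id=str(row["lane_id"]),
            i_free=float(row["i_free"]),
            i_sox=float(row["i_sox"]),
            i_pax=float(row["i_pax"]),
            i_dimer=float(row["i_dimer"]),
        )
        est = estimate_omega(normalize_lane(lane), epsilon=epsilon)
        rows.append(
            {
                "lane_id": lane.lane_id,
                "element": row.get("element", ""),
                "replicate": row.get("replicate", ""),
                "omega": est.omega,
                "log2_omega": est.log2_omega,
                "reliable": est.reliable,
                "unreliable_reason": est.unreliable_reason,
            }
        )
    return pd.DataFrame(rows)
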