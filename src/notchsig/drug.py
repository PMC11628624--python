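"""Drug-screen analytics: plate QC, 4PL dose-response fits, HSA synergy.

Responses are percent inhibition relative to a vehicle (0%) and a
max-kill (100%) anchor. The four-parameter logistic is fitted on the
log10-dose scale with multi-start least squares; the Hill-slope window
used for hit filtering is strict on both sides. Synergy is scored against
the highest-single-agent (HSA) reference: per-cell excess inhibition over
the better of the two monotherapies, averaged over combination cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "DoseMatrix",
    "SynergyResult",
    "zprime",
    "four_pl",
    "fit_4pl",
    "hill_filter",
    "hsa_score",
]


def zprime(positive: np.ndarray, negative: np.ndarray) -> float:
    """Z'-factor screening-window statistic.

    1 - 3*(sd_pos + sd_neg)/|mean_pos - mean_neg| with sample (n-1)
    standard deviations; > 0.5 indicates an excellent assay window.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 readings per control arm")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise ValueError("control means are identical; Z' undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def four_pl(dose, bottom, top, ic50, hill):
    """4PL response: bottom + (top-bottom) / (1 + (ic50/dose)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / dose) ** hill)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted dose-response curve with parameters and diagnostics."""

    doses: np.ndarray
    responses: np.ndarray
    bottom: float = np.nan
    top: float = np.nan
    ic50: float = np.nan
    hill: float = np.nan
    rss: float = np.nan
    converged: bool = False

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "bottom": self.bottom,
                "top": self.top,
                "ic50": self.ic50,
                "hill": self.hill,
                "rss": self.rss,
                "converged": self.converged,
            }
        )


def fit_4pl(
    doses,
    responses,
    bottom_bounds: tuple[float, float] = (-20.0, 50.0),
    top_bounds: tuple[float, float] = (50.0, 120.0),
    hill_max: float = 10.0,
) -> DoseResponseCurve:
    """Least-squares 4PL fit with multi-start initialization.

    Fitted on the log10-dose scale for stability. IC50 is constrained to
    within 100x the tested dose range; degenerate inputs (near-constant
    responses) return converged=False instead of raising.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if (doses <= 0).any():
        raise ValueError("doses must be positive (omit the zero-dose anchor)")

    if np.ptp(responses) < 1e-9:  # flat curve: IC50/hill unidentifiable
        return DoseResponseCurve(
            doses=doses, responses=responses, rss=0.0, converged=False
        )

    log_d = np.log10(doses)
    lo_ic, hi_ic = log_d.min() - 2.0, log_d.max() + 2.0  # 100x beyond range

    def resid(theta):
        bottom, top, log_ic50, hill = theta
        pred = bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_ic50 - log_d)))
        return pred - responses

    lb = [bottom_bounds[0], top_bounds[0], lo_ic, 1e-3]
    ub = [bottom_bounds[1], top_bounds[1], hi_ic, hill_max]
    best = None
    for h0 in (0.5, 1.0, 2.0, 4.0):
        for lic0 in np.linspace(lo_ic + 0.5, hi_ic - 0.5, 5):
            x0 = [
                float(np.clip(responses.min(), *bottom_bounds)),
                float(np.clip(responses.max(), *top_bounds)),
                float(lic0),
                h0,
            ]
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub))
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return DoseResponseCurve(doses=doses, responses=responses, converged=False)
    bottom, top, log_ic50, hill = best.x
    rss = float(2 * best.cost)
    converged = bool(best.success and np.all(np.isfinite(best.x)))
    return DoseResponseCurve(
        doses=doses,
        responses=responses,
        bottom=float(bottom),
        top=float(top),
        ic50=float(10 ** log_ic50),
        hill=float(hill),
        rss=rss,
        converged=converged,
    )


def hill_filter(curve: DoseResponseCurve, lo: float = 0.5, hi: float = 5.0) -> bool:
    """Strict Hill-slope window: True iff lo < hill < hi."""
    if not curve.converged:
        raise ValueError("Hill filter requires a converged fit")
    return lo < curve.hill < hi


@dataclass(frozen=True)
class DoseMatrix:
    """Percent-inhibition matrix over a dose grid including the zero doses.

    Rows are doses of drug A (first entry 0), columns doses of drug B
    (first entry 0); row 0 / column 0 hold the monotherapy responses.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray  # shape (len(doses_a), len(doses_b))
    replicates: int = 1

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        inh = np.asarray(self.inhibition, dtype=float)
        if da[0] != 0 or db[0] != 0:
            raise ValueError("dose grids must start at 0 (monotherapy anchors)")
        if not (np.all(np.diff(da) > 0) and np.all(np.diff(db) > 0)):
            raise ValueError("dose grids must be strictly increasing")
        if inh.shape != (len(da), len(db)):
            raise ValueError("inhibition matrix shape does not match dose grids")
        if np.isnan(inh[:, 0]).any() or np.isnan(inh[0, :]).any():
            raise ValueError("missing monotherapy entries")
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "inhibition", inh)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.inhibition, index=self.doses_a, columns=self.doses_b
        )


@dataclass(frozen=True)
class SynergyResult:
    """Per-cell excess over the HSA reference and its mean over combos."""

    excess: np.ndarray  # NaN in monotherapy row/column
    score: float
    model: str = "hsa"


def hsa_score(matrix: DoseMatrix) -> SynergyResult:
    """Highest-single-agent synergy score.

    For every combination cell (i>0, j>0) the excess is the inhibition
    minus the larger of the two monotherapy inhibitions at those doses;
    the summary score is the arithmetic mean excess in percentage points.
    """
    inh = matrix.inhibition
    if inh.shape[0] < 2 or inh.shape[1] < 2:
        raise ValueError("matrix has no combination cells")
    mono_a = inh[1:, 0][:, None]  # column vector over drug-A doses
    mono_b = inh[0, 1:][None, :]
    ref = np.maximum(mono_a, mono_b)
    combo = inh[1:, 1:]
    excess_core = combo - ref
    excess = np.full_like(inh, np.nan)
    excess[1:, 1:] = excess_core
    return SynergyResult(excess=excess, score=float(np.nanmean(excess_core)))
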