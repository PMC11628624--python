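"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators cover the pipeline end to end: an expression cohort with
a planted fraction of signature-active samples and proportional-hazards
survival; paired ChIP peak sets with a planted summit co-localization
fraction; and dose matrices built from two 4PL monotherapies plus a
planted HSA excess. Every generator is reproducible from (config, seed)
and emits objects that satisfy the invariants of the analysis types.

Also hosts the caliper tumor-volume formula used in xenograft studies.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .drug import DoseMatrix, four_pl
from .peaks import PeakSet, RegionSet
from .stratify import ExpressionMatrix

__all__ = [
    "CohortSimConfig",
    "PeakSimConfig",
    "MatrixSimConfig",
    "simulate_cohort",
    "simulate_peak_pairs",
    "simulate_dose_matrix",
    "tumor_volume",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Patient-cohort generator settings.

    Expression is log2-scale: per-gene baselines ~ Normal(8, 2), noise
    Normal(0, noise_sd); signature genes are shifted up by ``effect``
    log2 units in the planted-active subset. Survival times follow a
    proportional-hazards model (exponential by default, Weibull via
    ``weibull_shape``) with hazard = baseline_hazard * HR^active and
    independent uniform administrative censoring calibrated to the
    requested fraction.
    """

    n_samples: int = 300
    active_fraction: float = 1 / 3
    effect: float = 1.5  # log2-unit shift on signature genes
    noise_sd: float = 0.5
    n_background_genes: int = 100
    hazard_ratio: float = 2.5
    baseline_hazard: float = 0.01  # events per month
    censoring_fraction: float = 0.3
    weibull_shape: float = 1.0  # 1.0 = exponential
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must lie in (0, 1)")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        for name in ("noise_sd", "hazard_ratio", "baseline_hazard", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _censor_horizon(cfg: CohortSimConfig) -> float:
    return _censor_horizon_cached(
        cfg.baseline_hazard,
        cfg.hazard_ratio,
        cfg.active_fraction,
        cfg.weibull_shape,
        cfg.censoring_fraction,
    )


@lru_cache(maxsize=256)
def _censor_horizon_cached(
    baseline_hazard: float,
    hazard_ratio: float,
    active_fraction: float,
    weibull_shape: float,
    censoring_fraction: float,
) -> float:
    """Uniform-censoring upper bound u giving the requested censored fraction.

    With C ~ U(0, u) independent of T, P(censored) = (1/u) ∫_0^u S(c) dc
    where S mixes the active and inactive survival functions; solved for
    u by bisection.
    """
    lam0 = baseline_hazard
    lam1 = baseline_hazard * hazard_ratio
    f = active_fraction
    k = weibull_shape

    def surv(c):
        return f * np.exp(-lam1 * c**k) + (1 - f) * np.exp(-lam0 * c**k)

    def censored_prob(u):
        val, _ = quad(surv, 0.0, u, limit=200)
        return val / u

    target = censoring_fraction
    lo, hi = 1e-6, 1.0
    while censored_prob(hi) > target:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to calibrate censoring horizon")
    return brentq(lambda u: censored_prob(u) - target, lo, hi)


def simulate_cohort(cfg: CohortSimConfig, sig):
    """Simulate an expression cohort with survival keyed to planted activity.

    Returns (ExpressionMatrix, survival DataFrame with sample/time/event,
    boolean truth Series of planted-active samples).
    """
    rng = np.random.default_rng(cfg.seed)
    sig_genes = list(sig)
    bg_genes = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    genes = sig_genes + bg_genes
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]

    n_active = int(round(cfg.active_fraction * cfg.n_samples))
    active = np.zeros(cfg.n_samples, dtype=bool)
    active[rng.choice(cfg.n_samples, size=n_active, replace=False)] = True

    baselines = rng.normal(8.0, 2.0, size=len(genes))
    values = baselines[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(len(genes), cfg.n_samples)
    )
    values[: len(sig_genes), active] += cfg.effect
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    lam = cfg.baseline_hazard * np.where(active, cfg.hazard_ratio, 1.0)
    # inverse-CDF draw; shape 1 reduces to the exponential
    times = (rng.exponential(1.0, cfg.n_samples) / lam) ** (1.0 / cfg.weibull_shape)
    if cfg.censoring_fraction > 0:
        horizon = _censor_horizon(cfg)
        cens = rng.uniform(0.0, horizon, cfg.n_samples)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(cfg.n_samples, dtype=int)
        obs = times
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time": obs,
            "event": event,
            "group": np.where(active, "active", "inactive"),
        }
    )
    truth = pd.Series(active, index=samples, name="active")
    return expr, clinical, truth


@dataclass(frozen=True)
class PeakSimConfig:
    """Paired-peak generator settings.

    A planted fraction of A peaks receives a B partner whose summit sits
    at the A summit plus truncated-normal jitter strictly inside the
    co-localization threshold; all remaining peaks and decoys are spaced
    at least 10x the threshold apart so they can never co-localize.
    """

    n_pairs: int = 2000
    coloc_fraction: float = 0.4
    jitter_sd: float = 100.0  # bp
    threshold: int = 500  # bp; must match the analysis threshold
    decoys_a: int = 0
    decoys_b: int = 0
    peak_half_width: int = 250
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.jitter_sd >= self.threshold:
            raise ValueError("jitter must be below the co-localization threshold")
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_peak_pairs(cfg: PeakSimConfig, regions: RegionSet | None = None):
    """Generate two peak sets with a planted co-localized fraction.

    Peaks occupy slots spaced 10x the threshold apart on one chromosome;
    co-localized B partners share their A peak's slot. Returns
    (PeakSet A, PeakSet B, RegionSet of the enhancer-like slots).
    """
    rng = np.random.default_rng(cfg.seed)
    spacing = 10 * cfg.threshold
    n_coloc = int(round(cfg.coloc_fraction * cfg.n_pairs))
    n_b_far = cfg.n_pairs - n_coloc + cfg.decoys_b  # B peaks without a partner
    n_slots = cfg.n_pairs + cfg.decoys_a + n_b_far

    if regions is not None:
        total = regions.total_length
        if total < n_slots * spacing:
            raise ValueError(
                f"infeasible placement: regions span {total} bp but "
                f"{n_slots} peaks need {n_slots * spacing} bp at "
                f"{spacing} bp separation"
            )

    offset = int(rng.integers(0, spacing))
    centers = offset + spacing * np.arange(n_slots) + spacing // 2
    rng.shuffle(centers)
    a_centers = centers[: cfg.n_pairs + cfg.decoys_a]
    far_centers = centers[cfg.n_pairs + cfg.decoys_a :]

    a_summits = a_centers.copy()
    # planted partners: A summit + truncated Normal(0, jitter), |d| < threshold
    deltas = np.empty(n_coloc, dtype=int)
    for i in range(n_coloc):
        while True:
            d = int(round(rng.normal(0.0, cfg.jitter_sd)))
            if abs(d) <= cfg.threshold - 1:
                deltas[i] = d
                break
    b_summits = np.concatenate([a_summits[:n_coloc] + deltas, far_centers])

    hw = cfg.peak_half_width
    a_set = PeakSet.from_summits(
        [cfg.chrom] * len(a_summits), a_summits, half_width=hw,
        scores=rng.uniform(1, 100, len(a_summits)),
    )
    b_set = PeakSet.from_summits(
        [cfg.chrom] * len(b_summits), b_summits, half_width=hw,
        scores=rng.uniform(1, 100, len(b_summits)),
    )
    slot_regions = RegionSet(
        pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "start": np.sort(centers) - spacing // 2,
                "end": np.sort(centers) + spacing // 2,
            }
        )
    )
    return a_set, b_set, slot_regions


@dataclass(frozen=True)
class MatrixSimConfig:
    """Dose-matrix generator: two 4PL monotherapies plus planted HSA excess."""

    params_a: tuple[float, float, float, float] = (0.0, 100.0, 1.0, 1.0)
    params_b: tuple[float, float, float, float] = (0.0, 100.0, 0.01, 1.0)
    doses_a: tuple[float, ...] = (0.0, 0.008, 0.04, 0.2, 1.0, 5.0, 25.0, 100.0)
    doses_b: tuple[float, ...] = (
        0.0, 8e-5, 4e-4, 2e-3, 0.01, 0.05, 0.25, 1.0,
    )
    delta: float = 0.0  # planted uniform excess, percentage points
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ValueError("dose grids must include the zero dose first")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_dose_matrix(cfg: MatrixSimConfig) -> DoseMatrix:
    """Build a % inhibition matrix: mono rows from each 4PL, combos = HSA + delta.

    Combination cells are max(mono_a, mono_b) + delta + Normal(0, noise),
    clipped to [0, 100]; monotherapy rows are noise-free.
    """
    rng = np.random.default_rng(cfg.seed)
    da = np.asarray(cfg.doses_a, dtype=float)
    db = np.asarray(cfg.doses_b, dtype=float)
    mono_a = np.concatenate([[0.0], four_pl(da[1:], *cfg.params_a)])
    mono_b = np.concatenate([[0.0], four_pl(db[1:], *cfg.params_b)])
    inh = np.zeros((len(da), len(db)))
    inh[:, 0] = mono_a
    inh[0, :] = mono_b
    ref = np.maximum(mono_a[1:, None], mono_b[None, 1:])
    noise = rng.normal(0.0, cfg.noise_sd, ref.shape) if cfg.noise_sd > 0 else 0.0
    inh[1:, 1:] = np.clip(ref + cfg.delta + noise, 0.0, 100.0)
    return DoseMatrix(doses_a=da, doses_b=db, inhibition=inh)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume in mm^3: length * width^2 / 2.

    By convention width is the smaller axis; arguments given the other
    way round are swapped.
    """
    if length < 0 or width < 0:
        raise ValueError("caliper measurements must be non-negative")
    if width > length:
        length, width = width, length
    return length * width**2 / 2.0
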