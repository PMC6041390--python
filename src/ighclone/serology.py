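"""Quantitative serology: ELISA relative units, cutoffs, dCt expression.

Anti-dsDNA ELISA readouts are calibrated against an internal standard
serum pool whose 1/200 starting dilution is assigned 100 relative units
(RU). Sample and standard optical-density (OD) curves are interpolated
piecewise-linearly in (log reciprocal dilution, OD) after isotonic
smoothing; a sample's RU is the ratio of the reciprocal dilutions at which
sample and standard reach a common reference OD (the midpoint of the
standard's dynamic range), scaled by the anchor units. Parallel curves
shifted by a titer factor f therefore map to f x 100 RU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression


@dataclass
class DilutionSeries:
    """OD readings of one serum across a reciprocal-dilution series."""

    sample_id: str
    dilutions: list[float]  # reciprocal factors, e.g. 100, 200, 400 ...
    od: list[float]

    def __post_init__(self) -> None:
        d = np.asarray(self.dilutions, dtype=float)
        o = np.asarray(self.od, dtype=float)
        if d.shape != o.shape or d.size < 2:
            raise ValueError(f"{self.sample_id}: need matching dilution/OD arrays of length >= 2")
        if not np.all(np.diff(d) > 0):
            raise ValueError(f"{self.sample_id}: dilutions must be strictly increasing")
        if not (np.all(np.isfinite(o)) and np.all(o >= 0)):
            raise ValueError(f"{self.sample_id}: ODs must be finite and non-negative")

    def smoothed_od(self) -> np.ndarray:
        """Isotonic (non-increasing in dilution) projection of the ODs."""
        iso = IsotonicRegression(increasing=False)
        return iso.fit_transform(np.log(self.dilutions), self.od)


@dataclass
class StandardCurve:
    series: DilutionSeries
    anchor_dilution: float = 200.0
    anchor_units: float = 100.0

    def __post_init__(self) -> None:
        if self.anchor_units <= 0:
            raise ValueError("anchor_units must be positive")
        d = self.series.dilutions
        if not (min(d) <= self.anchor_dilution <= max(d)):
            raise ValueError("anchor dilution outside the standard's range")


@dataclass
class RUResult:
    sample_id: str
    ru: float | None
    below_quantification: bool = False
    bounding_dilution: float | None = None


def _titer_at(series: DilutionSeries, od_ref: float) -> float | None:
    """Reciprocal dilution at which the smoothed curve crosses od_ref."""
    logd = np.log(np.asarray(series.dilutions, dtype=float))
    od = series.smoothed_od()
    if od_ref > od.max() or od_ref < od.min():
        return None
    # od is non-increasing in logd; reverse for np.interp
    return float(np.exp(np.interp(od_ref, od[::-1], logd[::-1])))


def reference_od(standard: StandardCurve) -> float:
    """Midpoint of the standard's dynamic OD range."""
    od = standard.series.smoothed_od()
    return float((od.max() + od.min()) / 2.0)


def relative_units(sample: DilutionSeries, standard: StandardCurve) -> RUResult:
    """Calibrate one sample against the standard curve.

    RU = anchor_units x titer(sample) / titer(standard), where titer is the
    interpolated reciprocal dilution at the reference OD. A sample whose
    curve never reaches the reference OD is reported below quantification
    with its bounding (highest informative) dilution.
    """
    od_ref = reference_od(standard)
    titer_std = _titer_at(standard.series, od_ref)
    if titer_std is None:
        raise ValueError("standard curve does not span its own reference OD")
    titer_sample = _titer_at(sample, od_ref)
    if titer_sample is None:
        smoothed = sample.smoothed_od()
        bound = sample.dilutions[0] if smoothed.max() < od_ref else sample.dilutions[-1]
        return RUResult(sample.sample_id, None, below_quantification=True, bounding_dilution=float(bound))
    ru = standard.anchor_units * titer_sample / titer_std
    return RUResult(sample.sample_id, float(ru))


def positivity_cutoff(control_rus: list[float]) -> float:
    """Positivity cutoff from a control panel: mean + 3 SD (sample SD)."""
    if len(control_rus) < 5:
        raise ValueError(f"need at least 5 control sera, got {len(control_rus)}")
    arr = np.asarray(control_rus, dtype=float)
    return float(arr.mean() + 3.0 * arr.std(ddof=1))


@dataclass
class CtTable:
    """Cycle thresholds of target and housekeeping gene for one sample."""

    sample_id: str
    ct_target: float
    ct_ref: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_ref):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.sample_id}: Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_ref


#: fold-change bins for the -/+/++/+++ expression categories
CATEGORY_THRESHOLDS = (0.01, 0.1, 0.5)


def relative_expression(
    ct: CtTable, calibrator: CtTable, thresholds: tuple[float, float, float] = CATEGORY_THRESHOLDS
) -> tuple[float, str]:
    """Relative dCt expression vs a calibrator, with categorical binning.

    fold = 2^-(dCt_sample - dCt_calibrator). Categories (artifact-defined
    bins, configurable): '-' below thresholds[0], '+' up to thresholds[1],
    '++' up to thresholds[2], '+++' at or above thresholds[2].
    """
    fold = float(2.0 ** -(ct.delta_ct - calibrator.delta_ct))
    lo, mid, hi = thresholds
    if fold < lo:
        category = "-"
    elif fold < mid:
        category = "+"
    elif fold < hi:
        category = "++"
    else:
        category = "+++"
    return fold, category


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_test(group_a: list[float], group_b: list[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the null is enumerated exactly over all
    assignments of the pooled (tie-aware, midrank) values to the two
    groups; larger samples use the normal approximation with tie
    correction. Returns (U of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[: a.size], a.size)
    if np.unique(pooled).size == 1:
        return u_obs, 1.0
    if pooled.size <= 12:
        idx = range(pooled.size)
        us = np.array(
            [_u_statistic(ranks[list(comb)], a.size) for comb in itertools.combinations(idx, a.size)]
        )
        p_low = np.mean(us <= u_obs)
        p_high = np.mean(us >= u_obs)
        return u_obs, float(min(1.0, 2.0 * min(p_low, p_high)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
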