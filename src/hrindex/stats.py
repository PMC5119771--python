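"""Aggregate method-comparison statistics.

Compares a treadmill VO2peak method (gas-exchange measured, or predicted
from treadmill parameters) against the heart-rate-index surrogate across a
collection of study-level data points: pooled mean ± SD summaries, signed
absolute and percent differences, Student's paired t-test, Bland-Altman
agreement (bias and 95% limits of agreement at ±1.96 SD of the paired
differences), ordinary-least-squares departure from the line of identity,
and a tertile-stratified comparison with tertiles formed on the surrogate.

The analysis unit is the study-level data point, each weighted equally by
default; optional n-weighting is available in :func:`pooled_summary`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateDesignError, DomainError, EmptySelectionError,
    InsufficientDataError, MissingDataError, PairingError,
)
from .model import hri_vo2, mets_from_hri
from .records import Arm, StudyRecord

__all__ = [
    "PooledSummary", "PairedTResult", "MethodComparison", "BlandAltmanResult",
    "IdentityFit", "TertileRow", "TertileReport", "ArmComparison",
    "pooled_summary", "percent_difference", "paired_t", "bland_altman",
    "identity_regression", "assign_tertiles", "compare_arm",
]

#: Normal quantile used for 95% limits of agreement (exactly 1.96, not a
#: t-quantile).
LOA_Z = 1.96


class PooledSummary(NamedTuple):
    mean: float
    sd: float  # NaN when undefined (fewer than 2 values)
    count: int


@dataclass(frozen=True)
class PairedTResult:
    """Student's paired t-test result.

    ``degenerate`` is set when the paired differences have zero variance:
    all-zero differences give t = 0, p = 1; a constant nonzero difference
    gives infinite t and p = 0.
    """

    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class MethodComparison:
    """Pooled treadmill-vs-surrogate comparison for one arm."""

    arm: Arm
    n_points: int
    tm_mean: float
    tm_sd: float
    hri_mean: float
    hri_sd: float
    abs_diff: float       # signed, tm_mean - hri_mean, METs
    pct_diff: float       # signed percent, relative to the stated reference
    reference: str        # 'hri' or 'treadmill'
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired method values."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass(frozen=True)
class IdentityFit:
    """OLS fit of one method on another, judged against the y = x line."""

    slope: float
    intercept: float
    r: float

    @property
    def slope_departure(self) -> float:
        """Slope minus 1: zero when the fit lies on the line of identity."""
        return self.slope - 1.0

    @property
    def intercept_departure(self) -> float:
        return self.intercept


@dataclass(frozen=True)
class TertileRow:
    tertile: int
    n_points: int
    tm_mean: float
    hri_mean: float
    pct_diff: float
    p_value: float


@dataclass(frozen=True)
class TertileReport:
    rows: tuple[TertileRow, ...]

    def __iter__(self):
        return iter(self.rows)


@dataclass(frozen=True)
class ArmComparison:
    """Everything :func:`compare_arm` computes for one arm."""

    comparison: MethodComparison
    bland_altman: BlandAltmanResult
    tertiles: TertileReport
    identity: IdentityFit | None
    tm_values: tuple[float, ...] = field(repr=False, default=())
    hri_values: tuple[float, ...] = field(repr=False, default=())


def pooled_summary(values: Sequence[float],
                   weights: Sequence[float] | None = None) -> PooledSummary:
    """Pooled mean, SD (n-1 denominator) and count.

    Unweighted by default: each data point counts once. With ``weights``
    (typically study sample sizes) a frequency-weighted mean and SD with
    denominator ``sum(w) - 1`` are returned. The SD is NaN (undefined)
    for a single value.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise EmptySelectionError("pooled_summary of an empty collection")
    if weights is None:
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size >= 2 else math.nan
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape:
            raise PairingError("weights must match values in length")
        mean = float(np.average(v, weights=w))
        if v.size >= 2 and w.sum() > 1:
            sd = float(math.sqrt((w * (v - mean) ** 2).sum() / (w.sum() - 1)))
        else:
            sd = math.nan
    return PooledSummary(mean=mean, sd=sd, count=int(v.size))


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference of ``value`` from ``reference``.

    ``100 * (value - reference) / reference``. E.g. a treadmill-predicted
    mean of 8.12 METs against a measured 6.51 METs is +24.7%.
    """
    if reference <= 0:
        raise DomainError(f"reference must be positive, got {reference!r}")
    return 100.0 * (value - reference) / reference


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Student's paired t-test (two-sided), pairing by position.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and ``df = n-1``.
    Zero-variance differences are flagged degenerate rather than raising:
    identical samples give t = 0, p = 1; a constant nonzero shift gives
    a signed infinite t and p = 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"paired samples differ in length: {x.size} vs {y.size}")
    if x.size < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        t = math.copysign(math.inf, d[0])
        return PairedTResult(t=t, df=n - 1, p=0.0, degenerate=True)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=t, df=n - 1, p=p)


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bland-Altman agreement of paired method values.

    Differences ``a - b`` are assessed against pair means ``(a + b)/2``;
    bias is the mean difference and the 95% limits of agreement are
    ``bias ± 1.96 * SD(differences)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise PairingError("pairs must be a sequence of (a, b) tuples")
    if arr.shape[0] < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - LOA_Z * sd, loa_high=bias + LOA_Z * sd,
        n_pairs=int(arr.shape[0]),
    )


def identity_regression(x: Sequence[float], y: Sequence[float]) -> IdentityFit:
    """OLS of ``y`` on ``x``, to be judged against the line of identity."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise PairingError("x and y differ in length")
    if xv.size < 3:
        raise InsufficientDataError("identity regression needs at least 3 points")
    if np.ptp(xv) == 0.0:
        raise DegenerateDesignError("zero variance in x: regression undefined")
    fit = sps.linregress(xv, yv)
    return IdentityFit(slope=float(fit.slope), intercept=float(fit.intercept),
                       r=float(fit.rvalue))


def assign_tertiles(reference_values: Sequence[float]) -> np.ndarray:
    """Rank-based split into tertiles 1 (lowest) to 3 (highest).

    Group sizes are ``n // 3`` with remainders allocated to the lowest
    tertiles first (n = 7 gives sizes 3/2/2); ties are broken by stable
    input order. Returns an integer label per input position.
    """
    v = np.asarray(reference_values, dtype=float)
    if v.size < 3:
        raise InsufficientDataError("tertiles need at least 3 values")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(v.size, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(v.size, dtype=int)
    start = 0
    for tertile, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = tertile
        start += size
    return labels


def _require(record: StudyRecord, fields: tuple[str, ...]) -> None:
    for f in fields:
        if getattr(record, f) is None:
            raise MissingDataError(
                f"study {record.study_id!r} is missing {f}",
                study_id=record.study_id, field=f,
            )


def compare_arm(records: Sequence[StudyRecord], arm: Arm | str,
                reference: Literal["hri", "treadmill"] = "hri",
                hri_pooling: Literal["per_point", "pooled_hr"] = "per_point",
                ) -> ArmComparison:
    """Full treadmill-vs-surrogate comparison for one arm.

    For every record in the arm the surrogate value is computed from that
    point's mean heart rates and paired with the treadmill VO2peak. Emits
    the pooled :class:`MethodComparison` (paired t included), the
    :class:`BlandAltmanResult`, a tertile-stratified report with tertiles
    formed on the surrogate values, and the identity-line OLS fit.

    Parameters
    ----------
    reference
        Denominator of percent differences: the surrogate (``"hri"``,
        default) or the treadmill method.
    hri_pooling
        How the pooled surrogate mean is formed: ``"per_point"`` (default)
        averages the per-point surrogate values; ``"pooled_hr"`` applies
        the index to the arm's pooled mean heart rates instead — a
        sensitivity analysis for the mean-of-ratios vs ratio-of-means
        ambiguity inherent in aggregate data.
    """
    arm = Arm(arm)
    members = [r for r in records if r.arm is arm]
    if not members:
        raise EmptySelectionError(f"no records in arm {arm.value!r}")
    for r in members:
        _require(r, ("hr_rest", "hr_max", "vo2peak"))
    tm = np.array([r.vo2peak for r in members], dtype=float)
    hri = np.array([hri_vo2(r) for r in members], dtype=float)

    tm_sum = pooled_summary(tm)
    hri_sum = pooled_summary(hri)
    hri_mean = hri_sum.mean
    if hri_pooling == "pooled_hr":
        mean_rest = float(np.mean([r.hr_rest for r in members]))
        mean_max = float(np.mean([r.hr_max for r in members]))
        hri_mean = mets_from_hri(mean_max / mean_rest)

    if reference == "hri":
        pct = percent_difference(tm_sum.mean, hri_mean)
    elif reference == "treadmill":
        pct = percent_difference(hri_mean, tm_sum.mean)
    else:
        raise DomainError(f"unknown reference {reference!r}")

    test = paired_t(tm, hri)
    comparison = MethodComparison(
        arm=arm, n_points=tm.size,
        tm_mean=tm_sum.mean, tm_sd=tm_sum.sd,
        hri_mean=hri_mean, hri_sd=hri_sum.sd,
        abs_diff=tm_sum.mean - hri_mean, pct_diff=pct, reference=reference,
        t_stat=test.t, df=test.df, p_value=test.p, degenerate=test.degenerate,
    )

    ba = bland_altman(list(zip(tm, hri)))

    rows = []
    if tm.size >= 3:
        labels = assign_tertiles(hri)
        for tertile in (1, 2, 3):
            mask = labels == tertile
            t_tm, t_hri = tm[mask], hri[mask]
            t_pct = (percent_difference(t_tm.mean(), t_hri.mean())
                     if reference == "hri"
                     else percent_difference(t_hri.mean(), t_tm.mean()))
            if mask.sum() >= 2:
                p = paired_t(t_tm, t_hri).p
            else:
                p = math.nan
            rows.append(TertileRow(
                tertile=tertile, n_points=int(mask.sum()),
                tm_mean=float(t_tm.mean()), hri_mean=float(t_hri.mean()),
                pct_diff=t_pct, p_value=p,
            ))

    identity = None
    if tm.size >= 3 and np.ptp(hri) > 0:
        identity = identity_regression(hri, tm)

    return ArmComparison(
        comparison=comparison, bland_altman=ba,
        tertiles=TertileReport(rows=tuple(rows)), identity=identity,
        tm_values=tuple(tm.tolist()), hri_values=tuple(hri.tolist()),
    )
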