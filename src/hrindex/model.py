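"""The heart-rate-index (HRI) surrogate model of oxygen uptake.

The HRI is the ratio of an activity heart rate (submaximal or maximal) to
the resting heart rate, ``HRI = HR_activity / HR_rest``. Fitted to aggregate
data from exercise-test studies, it predicts oxygen uptake in metabolic
equivalents through the linear relation

    METs = 6 * HRI - 5

so that rest (HRI = 1) corresponds to exactly 1 MET, and 1 MET of extra
effort corresponds to an HRI increment of 1/6. METs convert to mass-specific
oxygen uptake via the resting convention 1 MET = 3.5 mL O2·kg⁻¹·min⁻¹.

All functions operate on unrounded floats; rounding to print precision is a
reporting concern (see :mod:`hrindex.report`). Inputs outside the model's
physiological domain (activity HR below rest, nonpositive METs) raise
:class:`~hrindex.errors.DomainError` rather than extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import DomainError, MissingDataError

if TYPE_CHECKING:  # pragma: no cover
    from .records import StudyRecord

#: Slope and intercept of the METs-on-HRI relation.
HRI_SLOPE: float = 6.0
HRI_INTERCEPT: float = -5.0

#: Resting oxygen uptake defining 1 MET, in mL O2·kg⁻¹·min⁻¹.
ML_PER_MET: float = 3.5


@dataclass(frozen=True)
class HriEstimate:
    """One HRI-based oxygen-uptake estimate in all three units.

    Attributes
    ----------
    hri
        Heart-rate index (dimensionless, >= 1).
    mets
        Oxygen uptake in metabolic equivalents, ``6*hri - 5``.
    vo2_ml
        The same value in mL O2·kg⁻¹·min⁻¹, ``3.5*mets``.
    """

    hri: float
    mets: float
    vo2_ml: float

    @classmethod
    def from_hri(cls, hri: float) -> "HriEstimate":
        mets = mets_from_hri(hri)
        return cls(hri=hri, mets=mets, vo2_ml=mets_to_ml(mets))

    @classmethod
    def from_heart_rates(cls, hr_max: float, hr_rest: float) -> "HriEstimate":
        return cls.from_hri(heart_rate_index(hr_max, hr_rest))


def heart_rate_index(hr_max: float, hr_rest: float) -> float:
    """Ratio of activity heart rate to resting heart rate.

    Parameters
    ----------
    hr_max
        Activity (submaximal or maximal) heart rate, beats·min⁻¹.
    hr_rest
        Resting heart rate, beats·min⁻¹; must be positive.

    Returns
    -------
    float
        ``hr_max / hr_rest``, unrounded.

    Raises
    ------
    DomainError
        If ``hr_rest <= 0``, or ``hr_max < hr_rest`` (an activity heart
        rate below rest is not an exercise measurement).
    """
    if hr_rest <= 0:
        raise DomainError(f"resting heart rate must be positive, got {hr_rest!r}")
    if hr_max < hr_rest:
        raise DomainError(
            f"activity HR ({hr_max}) below resting HR ({hr_rest}): "
            "not an exercise measurement"
        )
    return hr_max / hr_rest


def mets_from_hri(hri: float) -> float:
    """Oxygen uptake in METs predicted from a heart-rate index.

    The relation is ``METs = 6*hri - 5``. Indices below 5/6 would map to a
    nonpositive oxygen uptake and are rejected; the model's intended domain
    is ``hri >= 1`` (activity at or above rest).
    """
    if hri <= 5.0 / 6.0:
        raise DomainError(
            f"HRI {hri!r} maps to a nonpositive MET value; model domain is hri >= 1"
        )
    return HRI_SLOPE * hri + HRI_INTERCEPT


def hri_from_mets(mets: float) -> float:
    """Heart-rate index corresponding to an oxygen uptake in METs.

    Exact inverse of :func:`mets_from_hri`: ``hri = (mets + 5) / 6``.
    E.g. 5, 10 and 15 METs correspond to indices 1.67, 2.5 and 3.33
    (2 dp), and an elite-athlete 19 METs to an index of 4.
    """
    if mets <= 0:
        raise DomainError(f"METs must be positive, got {mets!r}")
    return (mets - HRI_INTERCEPT) / HRI_SLOPE


def mets_to_ml(mets: float) -> float:
    """Convert METs to mL O2·kg⁻¹·min⁻¹ (1 MET = 3.5 mL)."""
    if mets < 0:
        raise DomainError(f"negative oxygen uptake: {mets!r}")
    return mets * ML_PER_MET


def ml_to_mets(ml: float) -> float:
    """Convert mL O2·kg⁻¹·min⁻¹ to METs (exact inverse of :func:`mets_to_ml`)."""
    if ml < 0:
        raise DomainError(f"negative oxygen uptake: {ml!r}")
    return ml / ML_PER_MET


def hri_vo2(record: "StudyRecord") -> float:
    """HRI-predicted oxygen uptake (METs) for one study record.

    Composes :func:`heart_rate_index` and :func:`mets_from_hri` on the
    record's mean resting and maximal heart rates.

    Raises
    ------
    MissingDataError
        If the record lacks ``hr_rest`` or ``hr_max``; the message names
        the missing field and the study.
    """
    for field in ("hr_rest", "hr_max"):
        if getattr(record, field) is None:
            raise MissingDataError(
                f"study {record.study_id!r} is missing {field}",
                study_id=record.study_id, field=field,
            )
    return mets_from_hri(heart_rate_index(record.hr_max, record.hr_rest))
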