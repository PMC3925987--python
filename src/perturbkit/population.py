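"""Exact bias metrics on a fully specified stratified population.

The "truth" layer: an unmeasured factor U with L levels partitions the
population into strata. Within stratum i we know the stratum size ``m_i``,
the exposure prevalence ``p_i``, the disease risk among the unexposed
``r_i^u`` and the stratum relative risk ``rr_i`` (so the exposed risk is
``r_i^e = r_i^u * rr_i``). From these the crude risk ratio, the
standardized risk ratio (SRR, total population as the standard) and the
confounding risk ratio (CRR = crude RR / SRR) are exact arithmetic, not
estimates.

The crude RR compares the prevalence-weighted average risks::

    crude RR = r_bar_e / r_bar_u
    r_bar_e  = sum_i m_i p_i r_i^e     / sum_i m_i p_i
    r_bar_u  = sum_i m_i (1-p_i) r_i^u / sum_i m_i (1-p_i)

while the SRR compares the counterfactual case totals were everyone
exposed vs. everyone unexposed::

    SRR = sum_i m_i r_i^e / sum_i m_i r_i^u

CRR > 1 means the unmeasured factor inflates the crude association
(positive confounding); CRR < 1 means it masks it (negative confounding).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateExposureError, DegenerateRiskError, ValidationError

__all__ = [
    "StratifiedPopulation",
    "BiasSummary",
    "ConfoundingDirection",
    "crude_rr",
    "srr",
    "bias_summary",
]

#: |log CRR| below this is classified as "none": float noise must not
#: flip the confounding-direction label.
DIRECTION_TOL = 1e-9


class ConfoundingDirection(str, enum.Enum):
    POSITIVE = "positive_confounding"
    NEGATIVE = "negative_confounding"
    NONE = "none"


@dataclass(frozen=True)
class StratifiedPopulation:
    """A population stratified by an unmeasured factor U with L > 1 levels.

    Parameters
    ----------
    m : array-like of shape (L,)
        Stratum sizes. Positive reals: expected counts are accepted, the
        populations here are parameterized rather than enumerated.
    p : array-like of shape (L,)
        Exposure prevalence per stratum, each in (0, 1).
    r_u : array-like of shape (L,)
        Disease risk among the unexposed per stratum, each in (0, 1).
    rr : array-like of shape (L,)
        Stratum relative risk; the exposed risk ``r_u * rr`` must lie in
        (0, 1].
    """

    m: np.ndarray
    p: np.ndarray
    r_u: np.ndarray
    rr: np.ndarray
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for attr in ("m", "p", "r_u", "rr"):
            object.__setattr__(
                self, attr, np.asarray(getattr(self, attr), dtype=float)
            )
        L = self.m.shape[0]
        if L < 2:
            raise ValidationError(f"need L > 1 strata, got L={L}")
        for attr in ("p", "r_u", "rr"):
            if getattr(self, attr).shape != (L,):
                raise ValidationError(
                    f"'{attr}' has shape {getattr(self, attr).shape}, expected ({L},)"
                )
        if not np.all(self.m > 0):
            raise ValidationError("stratum sizes m must be positive")
        if not (np.all(self.p > 0) and np.all(self.p < 1)):
            raise ValidationError("exposure prevalences p must lie in (0, 1)")
        if not (np.all(self.r_u > 0) and np.all(self.r_u < 1)):
            raise ValidationError("unexposed risks r_u must lie in (0, 1)")
        r_e = self.r_u * self.rr
        if not (np.all(r_e > 0) and np.all(r_e <= 1)):
            raise ValidationError("exposed risks r_u * rr must lie in (0, 1]")

    @property
    def L(self) -> int:
        """Number of U strata."""
        return self.m.shape[0]

    @property
    def r_e(self) -> np.ndarray:
        """Disease risk among the exposed per stratum."""
        return self.r_u * self.rr

    @property
    def q(self) -> np.ndarray:
        """Exposure odds per stratum, p/(1-p)."""
        return self.p / (1.0 - self.p)

    @property
    def total(self) -> float:
        return float(self.m.sum())

    @property
    def p_bar(self) -> float:
        """Overall exposure prevalence."""
        return float(np.sum(self.m * self.p) / self.m.sum())

    @property
    def q_bar(self) -> float:
        """Overall exposure odds."""
        pb = self.p_bar
        return pb / (1.0 - pb)

    @property
    def r_bar_u(self) -> float:
        """Overall disease risk among the unexposed."""
        w = self.m * (1.0 - self.p)
        if w.sum() <= 0:
            raise DegenerateExposureError("no unexposed subjects in population")
        return float(np.sum(w * self.r_u) / w.sum())

    @property
    def r_bar_e(self) -> float:
        """Overall disease risk among the exposed."""
        w = self.m * self.p
        if w.sum() <= 0:
            raise DegenerateExposureError("no exposed subjects in population")
        return float(np.sum(w * self.r_e) / w.sum())


@dataclass(frozen=True)
class BiasSummary:
    """Crude RR, SRR and their ratio (the confounding RR) for one population."""

    crude_rr: float
    srr: float
    crr: float
    direction: ConfoundingDirection

    def __post_init__(self) -> None:
        rel = abs(self.crr * self.srr - self.crude_rr) / self.crude_rr
        if rel > 1e-12:
            raise ValidationError("crr must equal crude_rr / srr")


def crude_rr(pop: StratifiedPopulation) -> float:
    """Crude risk ratio ``r_bar_e / r_bar_u``, ignoring the U strata."""
    rbu = pop.r_bar_u
    if rbu <= 0:
        raise DegenerateRiskError("overall unexposed risk is zero")
    return pop.r_bar_e / rbu


def srr(pop: StratifiedPopulation) -> float:
    """Standardized risk ratio with the total population as the standard."""
    denom = float(np.sum(pop.m * pop.r_u))
    if denom <= 0:
        raise DegenerateRiskError("standardized unexposed case total is zero")
    return float(np.sum(pop.m * pop.r_e)) / denom


def bias_summary(pop: StratifiedPopulation, tol: float = DIRECTION_TOL) -> BiasSummary:
    """Classify the confounding bias of the unmeasured factor.

    Returns the crude RR, the SRR, the confounding risk ratio
    CRR = crude RR / SRR, and the direction: positive confounding when
    crude RR > SRR, negative when crude RR < SRR, none when
    ``|log CRR| < tol``.
    """
    c = crude_rr(pop)
    s = srr(pop)
    crr = c / s
    log_crr = np.log(crr)
    if abs(log_crr) < tol:
        direction = ConfoundingDirection.NONE
    elif log_crr > 0:
        direction = ConfoundingDirection.POSITIVE
    else:
        direction = ConfoundingDirection.NEGATIVE
    return BiasSummary(crude_rr=c, srr=s, crr=crr, direction=direction)
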