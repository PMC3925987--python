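"""Risk-ratio standardization on an observed stratifying variable.

Standardizing on a variable with V levels replaces the crude comparison
with a level-weighted one::

    adjusted RR = sum_j n_j s_j^e / sum_j n_j s_j^u

where n_j is the number of subjects at level j and s_j^e, s_j^u the
exposed/unexposed disease risks within that level. When the levels are
the values of a single binary perturbation variable this quantifies how
much one weak proxy of the unmeasured factor perturbs the crude RR;
when they are clusters of the whole PV panel it is the perturbation
adjustment itself (see :mod:`perturbkit.cluster`).

The module also provides the exact population-scale version (expected
counts instead of sampled subjects) and the expectation curve of the mean
log adjusted RR as a function of the PV's variance fraction f_PV, which
shows the adjustment moving the estimate from the crude RR toward the
standardized RR for confounded populations and leaving it untouched for
unconfounded ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NonEstimableError, ValidationError
from .population import StratifiedPopulation, crude_rr
from .simulate import PVPanelSpec, SubjectPanel, draw_pv_prevalences

__all__ = [
    "Stratification",
    "adjusted_rr",
    "adjusted_rr_for_labels",
    "single_pv_adjusted_rr",
    "population_adjusted_rr",
    "expectation_curve",
]


@dataclass(frozen=True)
class Stratification:
    """Per-level subject counts and exposed/unexposed risks.

    A level is *valid* when both risks are estimable, i.e. it contains at
    least one exposed and at least one unexposed subject. Risks of
    invalid levels are stored as NaN.
    """

    n_j: np.ndarray
    s_e: np.ndarray
    s_u: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("n_j", "s_e", "s_u", "valid"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr)))
        V = self.n_j.shape[0]
        if not all(getattr(self, a).shape == (V,) for a in ("s_e", "s_u", "valid")):
            raise ValidationError("all Stratification vectors must share length V")
        ok = self.valid.astype(bool)
        if np.any((self.s_e[ok] < 0) | (self.s_e[ok] > 1)):
            raise ValidationError("valid exposed risks must lie in [0, 1]")
        if np.any((self.s_u[ok] < 0) | (self.s_u[ok] > 1)):
            raise ValidationError("valid unexposed risks must lie in [0, 1]")

    @property
    def V(self) -> int:
        return self.n_j.shape[0]

    @classmethod
    def from_labels(cls, e: np.ndarray, d: np.ndarray, labels: np.ndarray) -> "Stratification":
        """Tabulate risks over the levels of ``labels`` (any hashable codes)."""
        e = np.asarray(e)
        d = np.asarray(d)
        codes, inv = np.unique(np.asarray(labels), return_inverse=True)
        V = codes.shape[0]
        n_j = np.bincount(inv, minlength=V).astype(float)
        n_exp = np.bincount(inv, weights=e, minlength=V)
        n_unexp = n_j - n_exp
        cases_exp = np.bincount(inv, weights=e * d, minlength=V)
        cases_unexp = np.bincount(inv, weights=(1 - e) * d, minlength=V)
        valid = (n_exp > 0) & (n_unexp > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_e = np.where(valid, cases_exp / np.where(n_exp > 0, n_exp, np.nan), np.nan)
            s_u = np.where(valid, cases_unexp / np.where(n_unexp > 0, n_unexp, np.nan), np.nan)
        return cls(n_j=n_j, s_e=s_e, s_u=s_u, valid=valid)


def adjusted_rr(strat: Stratification, invalid_policy: str = "drop") -> float:
    """Directly standardized risk ratio over the levels of a stratification.

    Invalid levels (a missing exposed or unexposed group) are handled per
    ``invalid_policy``: ``"drop"`` removes them from both sums and warns
    with the dropped count; ``"collapse"`` merges each invalid level into
    the largest valid one before standardizing.
    """
    if invalid_policy not in ("drop", "collapse"):
        raise ValidationError(f"unknown invalid_policy {invalid_policy!r}")
    valid = strat.valid.astype(bool)
    if not valid.any():
        raise NonEstimableError("no stratum with both exposed and unexposed subjects")
    n_dropped = int((~valid & (strat.n_j > 0)).sum())
    n_j, s_e, s_u = strat.n_j[valid], strat.s_e[valid], strat.s_u[valid]
    if invalid_policy == "collapse" and n_dropped:
        # fold invalid subjects into the largest valid level, keeping its risks
        j = int(np.argmax(n_j))
        n_j = n_j.copy()
        n_j[j] += strat.n_j[~valid].sum()
    elif n_dropped:
        warnings.warn(
            f"dropped {n_dropped} stratum/strata without both exposure groups",
            stacklevel=2,
        )
    denom = float(np.sum(n_j * s_u))
    if denom <= 0:
        raise NonEstimableError("standardized unexposed case total is zero")
    return float(np.sum(n_j * s_e)) / denom


def adjusted_rr_for_labels(
    e: np.ndarray, d: np.ndarray, labels: np.ndarray, invalid_policy: str = "drop"
) -> float:
    """Standardize the subject-level risk ratio on an arbitrary label vector."""
    return adjusted_rr(Stratification.from_labels(e, d, labels), invalid_policy)


def single_pv_adjusted_rr(
    panel: SubjectPanel, k: int, invalid_policy: str = "drop"
) -> float:
    """Adjusted RR standardizing on the k-th PV of the panel (0-based)."""
    if panel.pv is None or not 0 <= k < panel.m_pv:
        raise ValidationError(f"panel has no PV column {k}")
    return adjusted_rr_for_labels(panel.e, panel.d, panel.pv[:, k], invalid_policy)


def population_adjusted_rr(
    pop: StratifiedPopulation, pv_prev: np.ndarray
) -> float:
    """Exact (expected-count) adjusted RR after standardizing on one binary PV.

    ``pv_prev`` gives the PV prevalence in each U stratum; the PV is
    assigned independently of exposure and disease within stratum. Expected
    counts for the two PV levels are accumulated across strata and fed
    through the standardization formula. With a constant ``pv_prev`` the
    result collapses exactly to the crude RR.
    """
    prev = np.asarray(pv_prev, dtype=float)
    if prev.shape != (pop.L,):
        raise ValidationError(f"pv_prev must have length L={pop.L}")
    if np.any((prev < 0) | (prev > 1)):
        raise ValidationError("pv_prev entries must lie in [0, 1]")
    vals = _population_adjusted_rr_batch(pop, prev[None, :])
    return float(vals[0])


def _population_adjusted_rr_batch(
    pop: StratifiedPopulation, prev: np.ndarray
) -> np.ndarray:
    """Vectorized expected-count adjusted RR for S prevalence vectors (S, L)."""
    m, p, ru, re = pop.m, pop.p, pop.r_u, pop.r_e
    out = np.empty(prev.shape[0])
    for level, w in ((1, prev), (0, 1.0 - prev)):
        n_j = w @ m                      # subjects at this PV level
        exp_n = w @ (m * p)              # exposed subjects
        exp_c = w @ (m * p * re)         # exposed cases
        unexp_n = w @ (m * (1.0 - p))
        unexp_c = w @ (m * (1.0 - p) * ru)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_e = exp_c / exp_n
            s_u = unexp_c / unexp_n
        ok = (exp_n > 0) & (unexp_n > 0)
        term_e = np.where(ok, n_j * s_e, 0.0)
        term_u = np.where(ok, n_j * s_u, 0.0)
        if level == 1:
            num, den = term_e.copy(), term_u.copy()
        else:
            num += term_e
            den += term_u
    if np.any(den <= 0):
        raise NonEstimableError("degenerate PV prevalence: no estimable level")
    out[:] = num / den
    return out


def expectation_curve(
    pop: StratifiedPopulation,
    mu: float = 0.5,
    f_grid: np.ndarray | None = None,
    n_sims: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Mean log adjusted RR as a function of the PV variance fraction f_PV.

    For each f in the grid, draws ``n_sims`` per-stratum prevalence
    vectors from the beta with mean ``mu`` and variance fraction f, and
    averages the exact expected-count log adjusted RR. At f = 0 the curve
    equals log crude RR with zero spread; for a positively confounded
    population the mean decreases with f (toward log SRR), for a
    negatively confounded one it increases.

    Returns a DataFrame with columns ``f``, ``mean_log_adj_rr``, ``se``,
    ``n_used``.
    """
    rng = np.random.default_rng(rng)
    if f_grid is None:
        f_grid = np.arange(0.0, 0.1001, 0.005)
    log_crude = np.log(crude_rr(pop))
    rows = []
    for f in np.asarray(f_grid, dtype=float):
        if f == 0.0:
            rows.append((f, log_crude, 0.0, n_sims))
            continue
        spec = PVPanelSpec(m_pv=n_sims, mean=mu, f_pv=float(f))
        prev = draw_pv_prevalences(spec, pop.L, rng)
        vals = np.log(_population_adjusted_rr_batch(pop, prev))
        rows.append((f, float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals))), len(vals)))
    return pd.DataFrame(rows, columns=["f", "mean_log_adj_rr", "se", "n_used"])
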