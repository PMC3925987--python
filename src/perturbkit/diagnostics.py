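"""Bootstrap perturbation diagnostics.

With a finite panel (a few hundred PVs), one can still ask whether the
data show unmeasured confounding and in which direction: run the
perturbation adjustment on bootstrap resamples of the PV *columns* at a
grid of panel sizes and plot the mean adjusted RR against the number of
PVs used. A decreasing curve indicates positive confounding, an
increasing one negative confounding, a flat line its absence. Subjects
are never resampled — the bootstrap is over the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cluster import perturbation_adjusted_rr
from .errors import NonEstimableError, ValidationError
from .simulate import SubjectPanel

__all__ = ["DiagnosticCurve", "bootstrap_curve", "classify_trend", "default_m_grid"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosticCurve:
    """Bootstrapped mean adjusted RR per panel size, with standard errors."""

    m_grid: np.ndarray
    mean_adj_rr: np.ndarray
    se: np.ndarray
    n_boot: int
    n_dropped: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.m_grid)
        if not (self.mean_adj_rr.shape == g.shape and self.se.shape == g.shape):
            raise ValidationError("curve vectors must share the grid length")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")


def default_m_grid(m_max: int, n_points: int = 6) -> np.ndarray:
    """Roughly logarithmic grid of panel sizes from 10 up to ``m_max``."""
    lo = min(10, m_max)
    grid = np.unique(np.round(np.geomspace(lo, m_max, n_points)).astype(int))
    return grid


def bootstrap_curve(
    panel: SubjectPanel,
    m_grid: np.ndarray | None = None,
    n_boot: int = 1000,
    n_c: int = 20,
    rng: np.random.Generator | int | None = None,
) -> DiagnosticCurve:
    """Mean perturbation-adjusted RR over bootstrapped sub-panels.

    For each size m in the grid and each replicate, m PV columns are
    sampled with replacement from the panel and the perturbation
    adjustment is run on the resampled panel; replicates are drawn
    independently per (size, replicate). Non-estimable replicates are
    dropped and counted.
    """
    if panel.pv is None or panel.m_pv < 1:
        raise ValidationError("panel must carry at least one PV")
    if m_grid is None:
        m_grid = default_m_grid(panel.m_pv)
    m_grid = np.asarray(m_grid, dtype=int)
    if np.any(m_grid < 1):
        raise ValidationError("m_grid entries must be >= 1")
    rng = np.random.default_rng(rng)
    e, d = panel.e, panel.d
    means = np.empty(m_grid.shape[0])
    ses = np.empty(m_grid.shape[0])
    dropped = np.zeros(m_grid.shape[0], dtype=int)
    for gi, m in enumerate(m_grid):
        vals = []
        for _ in range(n_boot):
            cols = rng.integers(0, panel.m_pv, size=m)
            sub = SubjectPanel(e=e, d=d, pv=panel.pv[:, cols])
            try:
                rr, _ = perturbation_adjusted_rr(sub, n_c=n_c)
            except NonEstimableError:
                dropped[gi] += 1
                continue
            vals.append(rr)
        if not vals:
            raise NonEstimableError(f"all replicates non-estimable at m={m}")
        v = np.asarray(vals)
        means[gi] = v.mean()
        ses[gi] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    if dropped.any():
        logger.info("bootstrap_curve dropped replicates per size: %s", dropped.tolist())
    return DiagnosticCurve(
        m_grid=m_grid, mean_adj_rr=means, se=ses, n_boot=n_boot, n_dropped=dropped
    )


def classify_trend(curve: DiagnosticCurve) -> str:
    """Classify the diagnostic curve as decreasing, increasing or flat.

    Fits the slope of the mean adjusted RR on log panel size; the slope's
    uncertainty is propagated from the per-point bootstrap standard
    errors, and |slope| below twice that uncertainty reads as flat.
    """
    if curve.m_grid.shape[0] < 3:
        raise ValidationError("need at least 3 grid points to classify a trend")
    x = np.log(curve.m_grid.astype(float))
    y = curve.mean_adj_rr
    xc = x - x.mean()
    sxx = float(np.sum(xc * xc))
    slope = float(np.sum(xc * y)) / sxx
    slope_se = float(np.sqrt(np.sum((xc / sxx) ** 2 * curve.se**2)))
    if abs(slope) < 2.0 * slope_se or slope == 0.0:
        return "flat"
    return "decreasing" if slope < 0 else "increasing"
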