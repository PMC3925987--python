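"""Simulation of subject panels with perturbation variables (PVs).

A PV is a cheap binary variable associated with exposure and disease only
through the unmeasured factor U: its prevalence differs across U strata
but, conditional on U, it is independent of everything else. The
generative model here mirrors that structure:

1. each subject's U stratum is drawn proportional to stratum size, then
   exposure E ~ Bernoulli(p_U) and disease D ~ Bernoulli(r_U^e or r_U^u);
2. each PV k gets a mean prevalence ``mu_k`` (fixed, or uniform on
   (0.05, 0.95)) and per-stratum prevalences drawn from the beta
   distribution with mean ``mu_k`` and variance ``f_pv * mu_k (1-mu_k)``
   — ``f_pv`` is the "variance fraction", the share of the maximal
   Bernoulli variance that the across-strata spread of the prevalence
   takes up (f_pv = 0: the PV carries no information about U);
3. subjects' PV values are Bernoulli draws at their stratum's prevalence,
   independent across PVs, or chained by a first-order Markov dependence
   with a fixed odds ratio between successive PVs.

The latent stratum labels are kept for scoring only: estimation code in
this package never receives them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import StratifiedPopulation

__all__ = [
    "PVPanelSpec",
    "SubjectPanel",
    "beta_params_from_mean_varfrac",
    "draw_pv_prevalences",
    "sample_subjects",
    "attach_pvs",
    "simulate_panel",
]

#: Prevalences are clipped to this open interval; the beta can land
#: arbitrarily close to 0/1, which would create degenerate Bernoulli strata.
PREV_EPS = 1e-6


@dataclass(frozen=True)
class PVPanelSpec:
    """Generative description of a panel of binary perturbation variables.

    Parameters
    ----------
    m_pv : int
        Panel size (number of PVs), >= 1.
    mean : float or None
        Fixed mean prevalence mu for every PV; ``None`` draws each PV's
        mean from ``Uniform(mean_range)``.
    mean_range : pair of floats
        Support of the uniform mean law, default (0.05, 0.95).
    f_pv : float
        Variance fraction in [0, 1). 0 makes every PV pure noise
        (constant prevalence across strata).
    mixture : sequence of (weight, mean, f) or None
        If given, each (PV, stratum) prevalence is drawn from this
        mixture of beta components instead of the single beta; the
        weights must sum to 1.
    markov_or : float or None
        ``None``: PVs independent within subject. Otherwise successive
        PVs are linked, within each U stratum, by the unique 2x2 joint
        distribution with the stated margins and this odds ratio.
    noise_fraction : float
        Fraction of PVs forced to f_pv = 0 (uninformative), chosen at
        random within the panel.
    """

    m_pv: int
    mean: float | None = 0.5
    mean_range: tuple[float, float] = (0.05, 0.95)
    f_pv: float = 0.05
    mixture: Sequence[tuple[float, float, float]] | None = None
    markov_or: float | None = None
    noise_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.m_pv < 1:
            raise ValidationError("m_pv must be >= 1")
        if not 0.0 <= self.f_pv < 1.0:
            raise ValidationError("f_pv must lie in [0, 1)")
        if self.mean is not None and not 0.0 < self.mean < 1.0:
            raise ValidationError("mean must lie in (0, 1)")
        if self.mixture is not None:
            w = np.array([c[0] for c in self.mixture], dtype=float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError("mixture weights must sum to 1")
            for _, mu, f in self.mixture:
                if not (0.0 < mu < 1.0 and 0.0 <= f < 1.0):
                    raise ValidationError("mixture components need mu in (0,1), f in [0,1)")
        if self.markov_or is not None and self.markov_or <= 0:
            raise ValidationError("markov_or must be positive")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValidationError("noise_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectPanel:
    """Observed subject-level data: exposure, outcome and the PV panel.

    ``pv`` is an (n, m) binary matrix. Optional categorical ``confounders``
    (a DataFrame aligned with the subjects) carry measured confounders for
    the stratified adjustment. The latent stratum labels live in the
    private ``_u_true`` field: simulation bookkeeping, deliberately not
    part of the estimation API.
    """

    e: np.ndarray
    d: np.ndarray
    pv: np.ndarray | None = None
    confounders: pd.DataFrame | None = None
    _u_true: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=np.int8)
        d = np.asarray(self.d, dtype=np.int8)
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "d", d)
        if e.ndim != 1 or d.shape != e.shape:
            raise ValidationError("e and d must be 1-d vectors of equal length")
        if not (np.isin(e, (0, 1)).all() and np.isin(d, (0, 1)).all()):
            raise ValidationError("e and d must be binary (0/1)")
        if self.pv is not None:
            pv = np.asarray(self.pv, dtype=np.int8)
            if pv.ndim != 2 or pv.shape[0] != e.shape[0]:
                raise ValidationError("pv must be an (n, m) matrix")
            if not np.isin(pv, (0, 1)).all():
                raise ValidationError("pv entries must be binary (0/1)")
            object.__setattr__(self, "pv", pv)
        if self.confounders is not None and len(self.confounders) != e.shape[0]:
            raise ValidationError("confounders must have one row per subject")

    @property
    def n(self) -> int:
        return self.e.shape[0]

    @property
    def m_pv(self) -> int:
        return 0 if self.pv is None else self.pv.shape[1]

    def truth(self) -> np.ndarray:
        """Latent U labels — for scoring simulations only, never estimation."""
        if self._u_true is None:
            raise ValidationError("panel carries no latent stratum labels")
        return self._u_true.copy()

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: ``id, E, D, PV1..PVm`` plus confounder columns."""
        data: dict[str, np.ndarray] = {
            "id": np.arange(1, self.n + 1),
            "E": self.e.astype(int),
            "D": self.d.astype(int),
        }
        for k in range(self.m_pv):
            data[f"PV{k + 1}"] = self.pv[:, k].astype(int)
        df = pd.DataFrame(data)
        if self.confounders is not None:
            for col in self.confounders.columns:
                df[col] = np.asarray(self.confounders[col])
        return df


def beta_params_from_mean_varfrac(mu: float, f: float) -> tuple[float, float]:
    """Beta(alpha, beta) with mean ``mu`` and variance ``f * mu * (1-mu)``.

    The unique such parameterization is ``alpha = mu (1/f - 1)``,
    ``beta = (1-mu)(1/f - 1)``. ``f = 0`` has no beta representation; the
    caller must use the constant-prevalence branch instead.
    """
    if not 0.0 < mu < 1.0:
        raise ValidationError("mu must lie in (0, 1)")
    if not 0.0 < f < 1.0:
        raise ValidationError("f must lie in (0, 1); f = 0 means a constant prevalence")
    s = 1.0 / f - 1.0
    return mu * s, (1.0 - mu) * s


def draw_pv_prevalences(
    spec: PVPanelSpec,
    L: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw an (m_pv, L) matrix of per-stratum PV prevalences.

    Each PV gets a mean from the spec's mean law; informative PVs then get
    L independent beta draws around that mean (or mixture draws), noise
    PVs a constant row. Entries are clipped to (PREV_EPS, 1 - PREV_EPS).
    """
    rng = np.random.default_rng(rng)
    m = spec.m_pv
    if spec.mean is None:
        lo, hi = spec.mean_range
        mus = rng.uniform(lo, hi, size=m)
    else:
        mus = np.full(m, spec.mean)

    noise = np.zeros(m, dtype=bool)
    if spec.noise_fraction > 0:
        k = int(round(spec.noise_fraction * m))
        noise[rng.choice(m, size=k, replace=False)] = True

    prev = np.empty((m, L))
    if spec.mixture is not None:
        w = np.array([c[0] for c in spec.mixture])
        comp_mu = np.array([c[1] for c in spec.mixture])
        comp_f = np.array([c[2] for c in spec.mixture])
        comp = rng.choice(len(w), size=(m, L), p=w)
        cm, cf = comp_mu[comp], comp_f[comp]
        with np.errstate(divide="ignore"):
            s = 1.0 / np.where(cf > 0, cf, np.nan) - 1.0
        draws = rng.beta(np.where(np.isnan(s), 1.0, cm * s),
                         np.where(np.isnan(s), 1.0, (1.0 - cm) * s))
        prev[:] = np.where(np.isnan(s), cm, draws)
    elif spec.f_pv == 0.0:
        prev[:] = mus[:, None]
    else:
        s = 1.0 / spec.f_pv - 1.0
        prev[:] = rng.beta(
            np.repeat(mus * s, L).reshape(m, L),
            np.repeat((1.0 - mus) * s, L).reshape(m, L),
        )
    prev[noise] = mus[noise, None]
    return np.clip(prev, PREV_EPS, 1.0 - PREV_EPS)


def sample_subjects(
    pop: StratifiedPopulation,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> SubjectPanel:
    """Randomly sample n subjects (E, D and latent U) from a population."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(rng)
    u = rng.choice(pop.L, size=n, p=pop.m / pop.m.sum())
    e = (rng.random(n) < pop.p[u]).astype(np.int8)
    risk = np.where(e == 1, pop.r_e[u], pop.r_u[u])
    d = (rng.random(n) < risk).astype(np.int8)
    return SubjectPanel(e=e, d=d, _u_true=u)


def _plackett_joint(p: np.ndarray, q: np.ndarray, odds_ratio: float) -> np.ndarray:
    """P(X=1, Y=1) of the unique 2x2 table with margins p, q and the
    given odds ratio (Plackett construction)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if odds_ratio == 1.0:
        return p * q
    a = odds_ratio - 1.0
    b = 1.0 + a * (p + q)
    disc = b * b - 4.0 * a * odds_ratio * p * q
    p11 = (b - np.sqrt(disc)) / (2.0 * a)
    lo = np.maximum(0.0, p + q - 1.0)
    hi = np.minimum(p, q)
    # the minus branch is the admissible root; clip float noise only
    assert np.all(p11 > lo - 1e-9) and np.all(p11 < hi + 1e-9)
    return np.clip(p11, lo, hi)


def attach_pvs(
    panel: SubjectPanel,
    prev: np.ndarray,
    markov_or: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> SubjectPanel:
    """Attach PV columns drawn from per-stratum prevalences.

    ``prev`` is (m_pv, L) with one column per U stratum. Independent mode
    draws each PV_k ~ Bernoulli(prev[k, U]) independently; Markov mode
    draws PV_1 from its marginal and each subsequent PV conditionally on
    its predecessor so that, within each stratum, successive PVs have the
    stated odds ratio while keeping their marginal prevalences.

    PVs are generated from U alone — without regard to E and D — which is
    exactly the structural assumption that makes them perturbation
    variables rather than ordinary confounders.
    """
    rng = np.random.default_rng(rng)
    prev = np.asarray(prev, dtype=float)
    u = panel.truth()
    if prev.ndim != 2 or prev.shape[1] <= u.max():
        raise ValidationError("prev must have one column per U stratum in the panel")
    n, m = panel.n, prev.shape[0]
    marg = prev[:, u].T  # (n, m) marginal prevalence per subject

    if markov_or is None or markov_or == 1.0:
        if markov_or is None:
            pv = (rng.random((n, m)) < marg).astype(np.int8)
        else:
            pv = _markov_chain_pvs(prev, u, 1.0, rng)
    else:
        pv = _markov_chain_pvs(prev, u, markov_or, rng)
    return replace(panel, pv=pv)


def _markov_chain_pvs(
    prev: np.ndarray, u: np.ndarray, odds_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    m, _ = prev.shape
    n = u.shape[0]
    pv = np.empty((n, m), dtype=np.int8)
    pv[:, 0] = rng.random(n) < prev[0, u]
    for k in range(1, m):
        p_prev, p_k = prev[k - 1], prev[k]  # margins per stratum
        p11 = _plackett_joint(p_prev, p_k, odds_ratio)
        cond1 = p11 / p_prev  # P(PV_k=1 | PV_{k-1}=1)
        cond0 = (p_k - p11) / (1.0 - p_prev)
        probs = np.where(pv[:, k - 1] == 1, cond1[u], cond0[u])
        pv[:, k] = rng.random(n) < probs
    return pv


def simulate_panel(
    pop: StratifiedPopulation,
    n: int,
    spec: PVPanelSpec,
    rng: np.random.Generator | int | None = None,
) -> SubjectPanel:
    """Sample n subjects from ``pop`` and attach a PV panel per ``spec``."""
    rng = np.random.default_rng(rng)
    panel = sample_subjects(pop, n, rng)
    prev = draw_pv_prevalences(spec, pop.L, rng)
    return attach_pvs(panel, prev, spec.markov_or, rng)
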