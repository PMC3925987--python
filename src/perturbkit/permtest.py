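"""The perturbation test.

Each PV in the panel, standardized on alone, yields an adjusted risk
ratio theta_k. If no unmeasured confounding is present, every theta_k
is centred on the crude RR; under confounding the adjustments all drift
the same way (toward the unknown standardized RR), so the dispersion

    T = (1/m) * sum_k (log theta_k - log crude RR)^2

grows. Because PVs may be mutually dependent, no chi-square reference is
used: the null distribution of T comes from permutations that hold the
PV panel fixed and jointly shuffle the (E, D) pairs across subjects —
which preserves the exposure-disease association and breaks only the
PV-(E, D) link, exactly the null being tested.

The operating characteristic summarizes a test's performance as its
power averaged over a Uniform(0, 1) significance level; it equals
1 - E[p-value], so 0.5 means no power and 1.0 perfect power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import NonEstimableError, ValidationError
from .simulate import SubjectPanel

__all__ = [
    "PerturbationTestResult",
    "t_statistic",
    "permutation_test",
    "operating_characteristic",
    "PerturbationTester",
]


@dataclass(frozen=True)
class PerturbationTestResult:
    """Observed statistic, permutation null and p-value."""

    t_obs: float
    theta: np.ndarray
    theta_valid: np.ndarray
    n_perm: int
    t_perm: np.ndarray
    p_value: float

    def critical_value(self, alpha: float = 0.05) -> float:
        """(1 - alpha) quantile of the permutation distribution of T."""
        if not 0.0 < alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        return float(np.quantile(self.t_perm, 1.0 - alpha))


def _log_crude_rr(e: np.ndarray, d: np.ndarray) -> float:
    n_exp = e.sum()
    n_unexp = e.shape[0] - n_exp
    if n_exp == 0 or n_unexp == 0:
        raise NonEstimableError("crude RR needs both exposed and unexposed subjects")
    c_exp = float(e @ d)
    c_unexp = float(d.sum() - c_exp)
    if c_exp == 0 or c_unexp == 0:
        raise NonEstimableError("crude RR needs cases in both exposure groups")
    return float(np.log((c_exp / n_exp) / (c_unexp / n_unexp)))


def _theta_batch(
    e_rows: np.ndarray,
    d_rows: np.ndarray,
    pv: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-PV adjusted RRs for B jointly permuted (E, D) rows.

    ``e_rows``/``d_rows`` are (B, n) matrices whose rows are exposure and
    case indicators (one row per permutation); ``pv`` is (n, m). Returns
    (B, m) adjusted RRs and validity flags. A PV level with no exposed or
    no unexposed subjects is dropped from both sums; theta is flagged
    invalid when its log is not finite.
    """
    n = pv.shape[0]
    pvf = pv.astype(float)
    ed_rows = e_rows * d_rows
    ud_rows = (1.0 - e_rows) * d_rows

    n1 = pvf.sum(axis=0)[None, :]           # (1, m) level-1 sizes
    n0 = n - n1
    exp1 = e_rows @ pvf                     # (B, m)
    exp0 = e_rows.sum(axis=1, keepdims=True) - exp1
    unexp1 = n1 - exp1
    unexp0 = n0 - exp0
    ce1 = ed_rows @ pvf
    ce0 = ed_rows.sum(axis=1, keepdims=True) - ce1
    cu1 = ud_rows @ pvf
    cu0 = ud_rows.sum(axis=1, keepdims=True) - cu1

    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.zeros_like(exp1)
        den = np.zeros_like(exp1)
        for nj, ex, un, ce, cu in (
            (n1, exp1, unexp1, ce1, cu1),
            (n0, exp0, unexp0, ce0, cu0),
        ):
            ok = (ex > 0) & (un > 0)
            num += np.where(ok, nj * ce / np.where(ex > 0, ex, 1.0), 0.0)
            den += np.where(ok, nj * cu / np.where(un > 0, un, 1.0), 0.0)
        theta = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    valid = (den > 0) & (num > 0)
    return theta, valid


def t_statistic(panel: SubjectPanel) -> tuple[float, np.ndarray]:
    """Observed perturbation statistic T and the per-PV adjusted RRs.

    T averages the squared log-deviations of the single-PV adjusted RRs
    from the crude RR over the PVs whose adjusted RR is estimable (the
    divisor is the valid count). Returns ``(t_obs, theta)`` with
    non-estimable thetas as NaN.
    """
    if panel.pv is None or panel.m_pv < 1:
        raise ValidationError("panel must carry at least one PV")
    e = panel.e.astype(float)
    d = panel.d.astype(float)
    log_crude = _log_crude_rr(e, d)
    theta, valid = _theta_batch(e[None, :], d[None, :], panel.pv)
    theta, valid = theta[0], valid[0]
    t = _t_from_theta(theta, valid, log_crude)
    return t, np.where(valid, theta, np.nan)


def _t_from_theta(theta: np.ndarray, valid: np.ndarray, log_crude: float) -> float:
    if not valid.any():
        raise NonEstimableError("no PV with an estimable adjusted RR")
    dev = np.log(theta[valid]) - log_crude
    return float(np.mean(dev * dev))


def permutation_test(
    panel: SubjectPanel,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PerturbationTestResult:
    """Permutation perturbation test for unmeasured confounding.

    The PV panel stays fixed; each permutation reassigns the subjects'
    (E, D) pairs — jointly, preserving their pairing — and recomputes T.
    The p-value uses the add-one convention
    ``(1 + #{T_perm >= T_obs}) / (n_perm + 1)``, so it is never zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if panel.pv is None or panel.m_pv < 1:
        raise ValidationError("panel must carry at least one PV")
    rng = np.random.default_rng(rng)
    e = panel.e.astype(float)
    d = panel.d.astype(float)
    log_crude = _log_crude_rr(e, d)  # invariant under joint (E, D) shuffles

    theta_o, valid_o = _theta_batch(e[None, :], d[None, :], panel.pv)
    t_obs = _t_from_theta(theta_o[0], valid_o[0], log_crude)

    perms = np.array([rng.permutation(panel.n) for _ in range(n_perm)])
    theta_p, valid_p = _theta_batch(e[perms], d[perms], panel.pv)
    any_valid = valid_p.any(axis=1)
    if not any_valid.all():
        raise NonEstimableError("a permutation produced no estimable PV")
    dev = np.where(valid_p, np.log(np.where(valid_p, theta_p, 1.0)) - log_crude, 0.0)
    t_perm = (dev * dev).sum(axis=1) / valid_p.sum(axis=1)

    p = (1.0 + float(np.sum(t_perm >= t_obs))) / (n_perm + 1.0)
    return PerturbationTestResult(
        t_obs=t_obs,
        theta=np.where(valid_o[0], theta_o[0], np.nan),
        theta_valid=valid_o[0],
        n_perm=n_perm,
        t_perm=t_perm,
        p_value=p,
    )


def operating_characteristic(p_values: np.ndarray) -> float:
    """Power averaged over a Uniform(0, 1) alpha level: ``1 - mean(p)``.

    Since Power(alpha) = Pr(p <= alpha), integrating over alpha gives
    1 - E[p]. Ranges from 0.5 (no power) to 1.0 (perfect power).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("p_values must be nonempty")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return float(1.0 - p.mean())


class PerturbationTester(BaseEstimator):
    """Scikit-learn style interface to the perturbation test.

    Parameters
    ----------
    n_permutations : int, default=999
        Number of joint (E, D) permutations for the null distribution.
    random_state : int, Generator or None
        Seed for the permutation stream.

    Attributes
    ----------
    t_obs_ : float
        Observed statistic.
    p_value_ : float
        Add-one permutation p-value.
    theta_ : ndarray
        Per-PV adjusted RRs (NaN where non-estimable).
    result_ : PerturbationTestResult
    """

    def __init__(self, n_permutations: int = 999, random_state=None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        """Run the test on PV matrix X (n, m) and y = (n, 2) [E, D]."""
        X = np.asarray(X)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != X.shape[0]:
            raise ValidationError("y must be an (n, 2) array of [E, D] columns")
        panel = SubjectPanel(e=y[:, 0], d=y[:, 1], pv=X)
        self.result_ = permutation_test(
            panel, n_perm=self.n_permutations, rng=self.random_state
        )
        self.t_obs_ = self.result_.t_obs
        self.p_value_ = self.result_.p_value
        self.theta_ = self.result_.theta
        self.n_features_in_ = X.shape[1]
        return self
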