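"""Dose-response analysis: percent conversion, 2-parameter log-logistic
IC50 fitting, and Cheng-Prusoff conversion to inhibition constants.

The model is the two-parameter log-logistic curve with fixed asymptotes
(0% bottom, 100% top):

    f(x) = 100 / (1 + exp(b * (ln x - ln e)))

where ``e`` is the midpoint (the IC50, in molar) and ``b`` the Hill-type
slope. Raw plate signals are first converted to percent activity relative
to high (100%) and low (0%) controls; values outside [0, 100] are kept -
the constrained asymptotes absorb them. Competition IC50s convert to Ki
via Cheng-Prusoff: Ki = IC50 / (1 + [L]/Kd).

Modeled after the statsmodels idiom: ``LogLogistic2(conc, percent)`` is a
model object whose ``fit()`` returns a results object carrying estimates,
standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .stats import DomainError

__all__ = [
    "DoseResponseData",
    "to_percent",
    "LogLogistic2",
    "LogLogistic2Results",
    "fit_ll2",
    "cheng_prusoff",
    "classify_hit",
    "HIT_THRESHOLDS",
]

#: Ki classification bounds in molar: confirmed below 15 uM, ambiguous
#: up to 50 uM, disproved above.
HIT_THRESHOLDS = (15e-6, 50e-6)


@dataclass
class DoseResponseData:
    """Concentration series with raw signals and plate controls."""

    concentrations: np.ndarray  # molar, > 0
    responses: np.ndarray  # raw signal
    high_control: float
    low_control: float

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise DomainError("concentrations and responses must align")
        if np.any(self.concentrations <= 0):
            raise DomainError("concentrations must be strictly positive")
        if len(np.unique(self.concentrations)) < 4:
            raise DomainError("need >= 4 distinct concentrations for fitting")

    def percent(self) -> np.ndarray:
        return to_percent(self.responses, self.high_control, self.low_control)


def to_percent(raw, high_control: float, low_control: float) -> np.ndarray:
    """Percent activity: 100 * (raw - low) / (high - low); not clipped."""
    if high_control == low_control:
        raise DomainError("high and low controls must differ")
    return 100.0 * (np.asarray(raw, dtype=float) - low_control) / (
        high_control - low_control
    )


def _curve(logx: np.ndarray, b: float, loge: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(np.clip(b * (logx - loge), -500, 500)))


@dataclass
class LogLogistic2Results:
    """Fit results: slope ``b``, midpoint ``e`` (= IC50, molar), errors."""

    b: float
    e: float
    bse: tuple  # standard errors of (b, ln e) from the Jacobian
    rss: float
    converged: bool
    n_obs: int
    model: "LogLogistic2" = field(repr=False, default=None)

    @property
    def params(self) -> tuple:
        return (self.b, self.e)

    @property
    def ic50(self) -> float:
        return self.e

    def predict(self, concentrations) -> np.ndarray:
        x = np.asarray(concentrations, dtype=float)
        return _curve(np.log(x), self.b, np.log(self.e))

    def ki(self, ligand_conc: float, ligand_kd: float) -> float:
        return cheng_prusoff(self.e, ligand_conc, ligand_kd)

    def summary(self) -> str:
        lines = [
            "Two-parameter log-logistic fit (bottom 0%, top 100%)",
            "====================================================",
            f"observations          {self.n_obs:>12d}",
            f"converged             {str(self.converged):>12s}",
            f"slope b               {self.b:>12.4g}  (se {self.bse[0]:.3g})",
            f"midpoint e = IC50 [M] {self.e:>12.4g}  (se ln e {self.bse[1]:.3g})",
            f"residual SS           {self.rss:>12.4g}",
        ]
        return "\n".join(lines)


class LogLogistic2:
    """Two-parameter log-logistic dose-response model, asymptotes fixed.

    Parameters
    ----------
    concentrations : array, molar, strictly positive
    percent : array, percent activity (may lie outside [0, 100])
    """

    def __init__(self, concentrations, percent):
        self.conc = np.asarray(concentrations, dtype=float)
        self.percent = np.asarray(percent, dtype=float)
        if self.conc.shape != self.percent.shape:
            raise DomainError("concentrations and responses must align")
        if np.any(self.conc <= 0):
            raise DomainError("concentrations must be strictly positive")
        if len(np.unique(self.conc)) < 4:
            raise DomainError("need >= 4 distinct concentrations")

    @classmethod
    def from_raw(cls, data: DoseResponseData) -> "LogLogistic2":
        return cls(data.concentrations, data.percent())

    def fit(self, n_starts: int = 5, gtol: float = 1e-10) -> LogLogistic2Results:
        """Multi-start trust-region least squares.

        Midpoint initializations are log-spaced across (and slightly
        beyond) the tested concentration range; slope starts at 1. The
        ``converged`` flag requires a successful solve with small final
        gradient; flat response data yields ``converged=False`` rather
        than an exception (the midpoint is unidentifiable there).
        """
        logx = np.log(self.conc)
        y = self.percent
        flat = np.ptp(y) < 1e-9

        def resid(theta):
            return _curve(logx, theta[0], theta[1]) - y

        best = None
        starts = np.linspace(logx.min() - np.log(10), logx.max() + np.log(10), n_starts)
        for loge0 in starts:
            try:
                sol = least_squares(resid, x0=[1.0, loge0], method="lm", gtol=gtol)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return LogLogistic2Results(
                b=np.nan, e=np.nan, bse=(np.nan, np.nan), rss=np.nan,
                converged=False, n_obs=y.size, model=self,
            )
        b, loge = best.x
        rss = float(2 * best.cost)
        grad_norm = float(np.linalg.norm(best.grad))
        converged = bool(best.success and grad_norm < 1e-3 and not flat)
        # asymptotic covariance from the Jacobian at the optimum
        bse = (np.nan, np.nan)
        dof = y.size - 2
        if dof > 0:
            JtJ = best.jac.T @ best.jac
            try:
                cov = np.linalg.inv(JtJ) * (rss / dof)
                bse = tuple(np.sqrt(np.maximum(np.diag(cov), 0.0)))
            except np.linalg.LinAlgError:
                pass
        return LogLogistic2Results(
            b=float(b), e=float(np.exp(loge)), bse=bse, rss=rss,
            converged=converged, n_obs=y.size, model=self,
        )


def fit_ll2(data) -> LogLogistic2Results:
    """Fit the 2-parameter log-logistic curve.

    Accepts a :class:`DoseResponseData` (raw signals with controls) or a
    (concentrations, percent) pair.
    """
    if isinstance(data, DoseResponseData):
        model = LogLogistic2.from_raw(data)
    else:
        conc, percent = data
        model = LogLogistic2(conc, percent)
    return model.fit()


def cheng_prusoff(ic50: float, ligand_conc: float, ligand_kd: float) -> float:
    """Ki = IC50 / (1 + [L]/Kd) for a competitive binding assay."""
    if ic50 <= 0:
        raise DomainError("IC50 must be positive")
    if ligand_conc < 0:
        raise DomainError("ligand concentration must be non-negative")
    if ligand_kd <= 0:
        raise DomainError("ligand Kd must be positive")
    return ic50 / (1.0 + ligand_conc / ligand_kd)


def classify_hit(ki: float, thresholds=HIT_THRESHOLDS) -> str:
    """Label a Ki: 'confirmed' (< 15 uM), 'ambiguous' (< 50 uM), else 'disproved'."""
    if ki <= 0:
        raise DomainError("Ki must be positive")
    confirmed, ambiguous_upper = thresholds
    if ki < confirmed:
        return "confirmed"
    if ki < ambiguous_upper:
        return "ambiguous"
    return "disproved"
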