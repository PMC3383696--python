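"""Closed-form empirical models used by the scenario analyses.

Three published relationships are wrapped here:

* bacterial production (BP) from primary production (PPr), a power law
  BP = 2.15 * PPr**0.649 fitted on 379 lake observations with a log10
  prediction RMSE of 0.348;
* areal phytoplankton production from lake total phosphorus (the OECD
  eutrophication-survey regression), represented as a smooth curve
  calibrated exactly to its four published predictions at
  TP = 5, 10, 15 and 20 ug L^-1 (199, 312, 399 and 471 mg C m^-2 d^-1);
* the fitted quantile function of areal hydraulic loading across a
  305-lake phosphorus-budget dataset, q_s = a*x/(1-x) with
  a = 45.8 L m^-2 d^-1 and x the percentile in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError

__all__ = [
    "PowerLawModel",
    "BP_FROM_PPR",
    "bacterial_production",
    "TpPprModel",
    "TP_PPR_ANCHORS",
    "ppr_from_tp",
    "QsQuantileModel",
    "QS_QUANTILE",
    "qs_quantile",
]


@dataclass(frozen=True)
class PowerLawModel:
    """y = coeff * x**expon with lognormal (base-10) prediction error."""

    coeff: float
    expon: float
    rmse_log10: float = 0.0
    n_fit: int | None = None

    def __post_init__(self):
        if self.coeff <= 0:
            raise DomainError("coeff must be positive")
        if self.rmse_log10 < 0:
            raise DomainError("rmse_log10 must be non-negative")

    def predict(self, x):
        if np.any(np.asarray(x) < 0):
            raise DomainError("power-law input must be non-negative")
        out = self.coeff * np.asarray(x, dtype=float) ** self.expon
        return float(out) if out.ndim == 0 else out

    def sample(self, x, rng: np.random.Generator):
        """Prediction with multiplicative 10**eps error, eps ~ N(0, RMSE)."""
        mu = self.predict(x)
        eps = rng.normal(0.0, self.rmse_log10, size=np.shape(x) or None)
        return mu * 10.0 ** eps


#: Bacterial production from areal primary production, mg C m^-2 d^-1.
BP_FROM_PPR = PowerLawModel(coeff=2.15, expon=0.649, rmse_log10=0.348, n_fit=379)


def bacterial_production(ppr, rng: np.random.Generator | None = None,
                         model: PowerLawModel = BP_FROM_PPR):
    """BP (mg C m^-2 d^-1) from PPr; stochastic when ``rng`` is given.

    The deterministic mode evaluates 2.15 * PPr**0.649; the stochastic mode
    multiplies by 10**eps with eps ~ Normal(0, 0.348), propagating the
    published prediction error of the fit.
    """
    if rng is None:
        return model.predict(ppr)
    return model.sample(ppr, rng)


#: Published predictions of the TP -> PPr regression (TP ug L^-1 ->
#: areal phytoplankton production, mg C m^-2 d^-1).  These four pairs are
#: the authoritative calibration for the curve below.
TP_PPR_ANCHORS: tuple[tuple[float, float], ...] = ((5.0, 199.0), (10.0, 312.0), (15.0, 399.0), (20.0, 471.0))


def _fit_log10_quadratic(anchors) -> np.ndarray:
    tp = np.array([a[0] for a in anchors])
    ppr = np.array([a[1] for a in anchors])
    t = np.log10(tp)
    design = np.vstack([np.ones_like(t), t, t * t]).T
    coef, *_ = np.linalg.lstsq(design, np.log10(ppr), rcond=None)
    return coef


@dataclass(frozen=True)
class TpPprModel:
    """Areal phytoplankton production as a function of total phosphorus.

    The source regression is represented as a quadratic in log10 space,
    log10(PPr) = c0 + c1*t + c2*t**2 with t = log10(TP), whose three
    coefficients are recovered from the four published anchor predictions
    at construction.  Construction fails if the curve does not reproduce
    every anchor to the nearest integer or is not strictly increasing on
    TP in [1, 100] ug L^-1.
    """

    anchors: tuple[tuple[float, float], ...] = TP_PPR_ANCHORS
    _coef: tuple[float, float, float] = field(init=False, repr=False)

    def __post_init__(self):
        coef = _fit_log10_quadratic(self.anchors)
        object.__setattr__(self, "_coef", tuple(coef))
        for tp, ppr in self.anchors:
            if round(self._eval(tp)) != round(ppr):
                raise DomainError(
                    f"TP-PPr curve fails its anchor at TP={tp}: "
                    f"{self._eval(tp):.2f} vs {ppr}"
                )
        grid = np.linspace(1.0, 100.0, 512)
        if np.any(np.diff(self._eval(grid)) <= 0):
            raise DomainError("TP-PPr curve must be strictly increasing on [1, 100]")

    def _eval(self, tp):
        c0, c1, c2 = self._coef
        t = np.log10(np.asarray(tp, dtype=float))
        out = 10.0 ** (c0 + c1 * t + c2 * t * t)
        return float(out) if out.ndim == 0 else out

    def predict(self, tp):
        if np.any(np.asarray(tp) <= 0):
            raise DomainError("tp must be strictly positive")
        return self._eval(tp)


_TP_PPR_DEFAULT = TpPprModel()


def ppr_from_tp(tp):
    """Areal phytoplankton production (mg C m^-2 d^-1) at TP (ug L^-1)."""
    return _TP_PPR_DEFAULT.predict(tp)


@dataclass(frozen=True)
class QsQuantileModel:
    """Fitted quantile function of areal hydraulic loading, q_s = a*x/(1-x).

    ``a`` (L m^-2 d^-1) is the median of the fitted distribution; the
    function diverges at x = 1, so percentiles are capped at ``x_cap``.
    Evaluating on Uniform(0, x_cap) percentiles makes this an
    inverse-transform sampler for the loading distribution.
    """

    a: float = 45.8
    x_cap: float = 0.999

    def __post_init__(self):
        if self.a <= 0:
            raise DomainError("a must be positive")
        if not 0.0 < self.x_cap < 1.0:
            raise DomainError("x_cap must be in (0, 1)")

    def quantile(self, x):
        xv = np.asarray(x, dtype=float)
        if np.any(xv <= 0) or np.any(xv > self.x_cap):
            raise DomainError(f"percentile must be in (0, {self.x_cap}]")
        out = self.a * xv / (1.0 - xv)
        return float(out) if out.ndim == 0 else out

    def sample(self, n: int, rng: np.random.Generator):
        if n <= 0:
            raise DomainError("n must be positive")
        return self.quantile(rng.uniform(0.0, self.x_cap, size=n))


QS_QUANTILE = QsQuantileModel()


def qs_quantile(x, model: QsQuantileModel = QS_QUANTILE):
    """Areal hydraulic load (L m^-2 d^-1) at percentile ``x`` in (0, x_cap]."""
    return model.quantile(x)
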