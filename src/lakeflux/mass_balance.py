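"""Steady-state CSTR mass balance for terrestrial DOC in lakes.

A lake is treated as a continuously stirred tank reactor at hydrologic
steady state.  Terrestrial dissolved organic carbon (t-DOC) enters with
the inflow at a flow-weighted concentration ``c_in`` and is either removed
in-lake by a single first-order sink (rate ``sigma``, combining photolysis,
bacterial metabolism and flocculation/sedimentation) or advected through
the outlet (rate ``rho``, the flushing rate).  The retained fraction is

    R = sigma / (sigma + rho)

and the outflow concentration is ``c_in * (1 - R)``.  An equivalent
parameterisation uses an apparent settling velocity ``v = sigma * depth``
against the areal hydraulic load ``q_s``: R = v / (v + q_s).

Units
-----
q_s          L m^-2 d^-1 (numerically identical to mm d^-1)
mean depth   m
rates        d^-1
HRT          d (exposed in years with 1 yr = 365 d)
fluxes       mg C m^-2 d^-1
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InconsistentHydrologyError, UndefinedBudgetError

MM_PER_M = 1000.0
DAYS_PER_YEAR = 365.0

#: Long-term whole-lake mass-balance estimate of the first-order t-DOC
#: loss rate (d^-1) and its between-study SD.  Decadal input/output budget
#: studies are given precedence over shorter incubation estimates.
SIGMA_TDOC = 0.0009
SIGMA_TDOC_SD = 0.0004


def _require_positive(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise DomainError(f"{name} must be strictly positive")


def _require_nonnegative(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise DomainError(f"{name} must be non-negative")


def flushing_from_hydraulics(qs, mean_depth):
    """Flushing rate rho (d^-1) = inflow / volume = q_s / (1000 * depth).

    ``qs`` is the areal hydraulic load in L m^-2 d^-1 (= mm d^-1) and
    ``mean_depth`` the lake mean depth in m; the reciprocal of the result
    is the hydraulic residence time in days.
    """
    _require_positive("qs", qs)
    _require_positive("mean_depth", mean_depth)
    return np.asarray(qs) / (MM_PER_M * np.asarray(mean_depth)) if np.ndim(qs) or np.ndim(mean_depth) else qs / (MM_PER_M * mean_depth)


def retention_fraction(sigma, rho):
    """Retained fraction R = sigma / (sigma + rho) of the input t-DOC flux.

    Strictly increasing in ``sigma`` and strictly decreasing in ``rho``;
    R -> 1 as the lake stops flushing and R -> 0 for flow-through systems.
    """
    _require_nonnegative("sigma", sigma)
    _require_nonnegative("rho", rho)
    s = np.asarray(sigma, dtype=float)
    r = np.asarray(rho, dtype=float)
    if np.any(s + r == 0):
        raise UndefinedBudgetError("retention undefined when sigma and rho are both zero")
    out = s / (s + r)
    return float(out) if out.ndim == 0 else out


def areal_doc_load(qs, c_in):
    """Areal t-DOC loading (mg C m^-2 d^-1) = q_s * input concentration."""
    _require_nonnegative("qs", qs)
    _require_nonnegative("c_in", c_in)
    out = np.asarray(qs, dtype=float) * np.asarray(c_in, dtype=float)
    return float(out) if out.ndim == 0 else out


def settling_velocity_form(v_doc, qs):
    """Retention via the settling-velocity parameterisation v/(v + q_s).

    ``v_doc`` must be expressed in the same length/time units as ``qs``
    (mm d^-1 by package convention).  Equals ``retention_fraction(sigma,
    rho)`` exactly when v = sigma * (1000 * mean_depth).
    """
    _require_nonnegative("v_doc", v_doc)
    _require_positive("qs", qs)
    out = np.asarray(v_doc, dtype=float) / (np.asarray(v_doc, dtype=float) + np.asarray(qs, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LakeHydrology:
    """Per-lake hydraulic state; rho * hrt_days == 1 by construction."""

    qs: float            # areal hydraulic load, L m^-2 d^-1
    mean_depth: float    # m
    rho: float           # flushing rate, d^-1
    hrt_days: float      # hydraulic residence time, d

    @property
    def hrt_years(self) -> float:
        return self.hrt_days / DAYS_PER_YEAR

    @classmethod
    def from_components(
        cls,
        qs: float | None = None,
        mean_depth: float | None = None,
        hrt_days: float | None = None,
        *,
        hrt_years: float | None = None,
        rtol: float = 1e-3,
    ) -> "LakeHydrology":
        """Build from any two of {q_s, mean depth, HRT}; derive the third.

        Supplying all three is allowed but they must agree to within
        ``rtol`` relative (default 0.1%), otherwise
        :class:`InconsistentHydrologyError` is raised.
        """
        if hrt_years is not None:
            if hrt_days is not None:
                raise DomainError("give hrt_days or hrt_years, not both")
            hrt_days = hrt_years * DAYS_PER_YEAR
        given = {"qs": qs, "mean_depth": mean_depth, "hrt_days": hrt_days}
        known = {k: v for k, v in given.items() if v is not None}
        if len(known) < 2:
            raise DomainError("need at least two of qs, mean_depth, hrt")
        for k, v in known.items():
            _require_positive(k, v)
        if qs is not None and mean_depth is not None:
            derived_hrt = MM_PER_M * mean_depth / qs
            if hrt_days is not None and not math.isclose(hrt_days, derived_hrt, rel_tol=rtol):
                raise InconsistentHydrologyError(
                    f"hrt_days={hrt_days:g} disagrees with qs/depth-implied {derived_hrt:g}"
                )
            hrt_days = derived_hrt
        elif qs is not None:  # qs + hrt
            mean_depth = qs * hrt_days / MM_PER_M
        else:  # depth + hrt
            qs = MM_PER_M * mean_depth / hrt_days
        return cls(qs=qs, mean_depth=mean_depth, rho=1.0 / hrt_days, hrt_days=hrt_days)


@dataclass(frozen=True)
class DocBudget:
    """Per-lake t-DOC accounting under the steady-state CSTR model."""

    loading: float          # mg C m^-2 d^-1
    sigma: float            # d^-1
    rho: float              # d^-1
    retention: float        # fraction in [0, 1]
    available_flux: float   # retained in-lake, mg C m^-2 d^-1
    advected_flux: float    # exported downstream, mg C m^-2 d^-1
    c_in: float | None = None   # mg C L^-1
    c_out: float | None = None  # mg C L^-1
    v_doc: float | None = None  # apparent settling velocity, mm d^-1


def split_budget(loading, sigma, rho, c_in=None, mean_depth=None) -> DocBudget:
    """Partition an areal t-DOC load into available (retained) and advected flux.

    available = loading * R, advected = loading * (1 - R) with
    R = sigma/(sigma + rho); the two parts sum to the loading exactly.
    Optionally records the outflow concentration (if ``c_in`` is given)
    and the apparent settling velocity (if ``mean_depth`` in m is given).
    """
    _require_nonnegative("loading", loading)
    r = retention_fraction(sigma, rho)
    available = loading * r
    return DocBudget(
        loading=loading,
        sigma=sigma,
        rho=rho,
        retention=r,
        available_flux=available,
        advected_flux=loading - available,
        c_in=c_in,
        c_out=None if c_in is None else c_in * (1.0 - r),
        v_doc=None if mean_depth is None else sigma * MM_PER_M * mean_depth,
    )


def budget_for_lake(hydro: LakeHydrology, c_in: float, sigma: float = SIGMA_TDOC) -> DocBudget:
    """Convenience wrapper: loading from q_s and c_in, split at the lake's rho."""
    loading = areal_doc_load(hydro.qs, c_in)
    return split_budget(loading, sigma, hydro.rho, c_in=c_in, mean_depth=hydro.mean_depth)
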