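"""Two-end-member fatty-acid mixing inference for consumer diets.

Herbivorous zooplankton fed known mixtures of a terrestrial (allochthonous)
and an algal (autochthonous) resource carry fatty-acid profiles that are,
to first order, linear mixtures of the profiles of consumers raised on the
two pure diets.  Because the algal end-member is strongly preferred, the
realized contribution of the autochthonous source exceeds its dietary
share.  This module solves the inverse problems:

* :func:`decompose_profile` - least-squares source weight from a full
  fatty-acid profile;
* :func:`omega_mixing` - source fraction from the omega-3:omega-6 ratio
  alone (two conventions, since ratio mixing is not physically linear);
* :func:`utilization_factor` - the odds-ratio measure of preferential
  utilization of the autochthonous end-member;
* :func:`fit_fqi` - the relative food-quality index of allochthonous
  matter (autochthonous baseline = 1) that best explains observed
  contributions across a diet gradient, by SSE minimisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import DomainError, UnidentifiableError

#: Default omega-3:omega-6 ratios of consumers raised on the pure
#: autochthonous (cryptophyte) and pure terrestrial diets.
OMEGA_RATIO_AUTO = 11.7
OMEGA_RATIO_ALLO = 1.6


@dataclass(frozen=True)
class FattyAcidProfile:
    """Proportional fatty-acid composition of a consumer under a known diet.

    ``fa_proportions`` maps fatty-acid names to proportions summing to 1;
    ``diet_allo_fraction`` is the dietary share of terrestrial POC.
    """

    treatment_id: str
    diet_allo_fraction: float
    fa_proportions: dict[str, float]
    omega_ratio: float

    def __post_init__(self):
        if not 0.0 <= self.diet_allo_fraction <= 1.0:
            raise DomainError("diet_allo_fraction must be in [0, 1]")
        vals = np.array(list(self.fa_proportions.values()), dtype=float)
        if np.any(vals < 0):
            raise DomainError("fatty-acid proportions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise DomainError(f"fatty-acid proportions must sum to 1 (got {vals.sum():.8f})")
        if self.omega_ratio <= 0:
            raise DomainError("omega_ratio must be positive")

    def vector(self, names: list[str] | None = None) -> np.ndarray:
        names = names or sorted(self.fa_proportions)
        return np.array([self.fa_proportions[n] for n in names], dtype=float)


@dataclass(frozen=True)
class MixingSolution:
    """Result of a two-end-member decomposition."""

    w_auto: float                       # realized autochthonous lipid fraction
    fit_r2: float
    utilization_factor: float | None = None   # odds ratio vs the diet, if defined


def _profile_r2(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def decompose_profile(
    mix: FattyAcidProfile,
    end_auto: FattyAcidProfile,
    end_allo: FattyAcidProfile,
) -> MixingSolution:
    """Least-squares source weight for a mixed-diet consumer profile.

    Finds w in [0, 1] minimising ||mix - (w*end_auto + (1-w)*end_allo)||^2
    (closed form, projection onto the segment between the end-members) and
    reports the r^2 of the reconstruction.  End-member profiles that are
    nearly collinear (r^2 >= 0.95) are rejected as unidentifiable.
    """
    names = sorted(mix.fa_proportions)
    if set(names) != set(end_auto.fa_proportions) or set(names) != set(end_allo.fa_proportions):
        raise DomainError("profiles must share the same fatty-acid names")
    m = mix.vector(names)
    a = end_auto.vector(names)
    b = end_allo.vector(names)
    if _profile_r2(a, b) >= 0.95:
        raise UnidentifiableError("end-member profiles are too similar to separate sources")
    d = a - b
    w = float(np.clip(np.dot(m - b, d) / np.dot(d, d), 0.0, 1.0))
    resid = m - (w * a + (1.0 - w) * b)
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    uf = None
    if 0.0 < w < 1.0 and 0.0 < mix.diet_allo_fraction < 1.0:
        uf = utilization_factor(w, mix.diet_allo_fraction)
    return MixingSolution(w_auto=w, fit_r2=r2, utilization_factor=uf)


def omega_mixing(
    r_mix: float,
    r_allo: float = OMEGA_RATIO_ALLO,
    r_auto: float = OMEGA_RATIO_AUTO,
    mode: str = "ratio",
) -> float:
    """Autochthonous fraction inferred from an omega-3:omega-6 ratio.

    ``mode="ratio"`` (default) interpolates linearly in the ratio itself:
    (r_mix - r_allo)/(r_auto - r_allo).  ``mode="pools"`` mixes the
    omega-3 and omega-6 pools linearly and computes the ratio afterwards,
    assuming equal total PUFA content in both end-members, then inverts.
    Both modes agree at the end-members and are monotone in ``r_mix``;
    values outside [r_allo, r_auto] are clamped with a warning.
    """
    if r_auto <= r_allo:
        raise DomainError("r_auto must exceed r_allo")
    if not r_allo <= r_mix <= r_auto:
        warnings.warn(f"omega ratio {r_mix:g} outside [{r_allo:g}, {r_auto:g}]; clamping")
        r_mix = min(max(r_mix, r_allo), r_auto)
    if mode == "ratio":
        return (r_mix - r_allo) / (r_auto - r_allo)
    if mode == "pools":
        # unit PUFA pools: omega3 = r/(1+r), omega6 = 1/(1+r)
        w3a, w6a = r_auto / (1 + r_auto), 1 / (1 + r_auto)
        w3t, w6t = r_allo / (1 + r_allo), 1 / (1 + r_allo)
        num = r_mix * w6t - w3t
        den = num - (r_mix * w6a - w3a)
        return float(num / den)
    raise DomainError(f"unknown omega mixing mode {mode!r}")


def utilization_factor(w_auto: float, diet_allo_fraction: float) -> float:
    """Preferential-utilization odds ratio of the autochthonous source.

    (w_auto / w_allo) / (d_auto / d_allo): how many times more of the
    consumer's lipid came from the algal source than its dietary share
    alone would predict.  Undefined for boundary diets or weights.
    """
    if not 0.0 < w_auto < 1.0:
        raise DomainError("utilization factor undefined for boundary w_auto")
    if not 0.0 < diet_allo_fraction < 1.0:
        raise DomainError("utilization factor undefined for boundary diets")
    return (w_auto / (1.0 - w_auto)) * (diet_allo_fraction / (1.0 - diet_allo_fraction))


def predicted_allochthony(p_allo, fqi_allo: float, fqi_auto: float = 1.0):
    """Quality-weighted consumer allochthony at resource share ``p_allo``."""
    p = np.asarray(p_allo, dtype=float)
    out = p * fqi_allo / (p * fqi_allo + (1.0 - p) * fqi_auto)
    return float(out) if out.ndim == 0 else out


def fit_fqi(
    observed_allochthony,
    diet_allo_fractions,
    below_half_only: bool = False,
    fqi_auto: float = 1.0,
) -> float:
    """Fit the allochthonous food-quality index to a diet-gradient experiment.

    ``observed_allochthony`` are the realized allochthonous contributions
    (1 - w_auto) per treatment; ``diet_allo_fractions`` the corresponding
    dietary shares.  Returns the scalar FQI in (0, 1] minimising the error
    sum of squares against the quality-weighting model, holding the
    autochthonous baseline at ``fqi_auto``.  ``below_half_only`` restricts
    the fit to treatments with dietary allochthonous share < 50%, the
    regime most representative of real lakes.
    """
    obs = np.asarray(observed_allochthony, dtype=float)
    p = np.asarray(diet_allo_fractions, dtype=float)
    if obs.shape != p.shape:
        raise DomainError("observed and diet arrays must have equal length")
    keep = (p > 0.0) & (p < 1.0)
    if below_half_only:
        keep &= p < 0.5
    if keep.sum() < 2:
        raise UnidentifiableError("need at least two interior diet treatments")
    obs, p = obs[keep], p[keep]

    def sse(f):
        return float(np.sum((obs - predicted_allochthony(p, f, fqi_auto)) ** 2))

    res = minimize_scalar(sse, bounds=(1e-9, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)
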