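"""Modified-Hill dose-response modelling with closed-form EC50.

The viability of drug-treated cells relative to an untreated reference is
modelled as

    R(D) = m * D**n / (k**n + D**n),        n <= 0

where ``D`` is the drug dose in nM, ``m`` is the zero-dose intercept
(``R -> m`` as ``D -> 0`` for n < 0), ``n`` controls steepness (more
negative = steeper decline) and ``k`` (nM) the curvature.  Setting
``R = 0.5`` and solving for ``D`` gives the closed-form half-maximal
effective concentration

    EC50 = k * (2*m - 1) ** (-1/n)

which exists only when the fitted intercept exceeds 0.5; otherwise the
curve never crosses half-maximal response and the EC50 is *not reached*.

Samples are classified as responders when their EC50 is finite and
strictly below 1000 nM (1 µM), the binary cutoff used throughout this
package for selinexor-type response calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ViabilityPlate",
    "HillFit",
    "Ec50Result",
    "ResponderLabel",
    "DegenerateReferenceError",
    "InvalidFitError",
    "evaluate_hill",
    "normalize_plate",
    "fit_hill",
    "compute_ec50",
    "ec50_root_find",
    "classify_responder",
    "RESPONDER_CUTOFF_NM",
]

#: binary responder cutoff (nM); EC50 strictly below this calls a responder
RESPONDER_CUTOFF_NM = 1000.0

#: optimizer start values: k = 1000 nM, m = 1, n = -1
HILL_INITIAL_GUESS = (1000.0, 1.0, -1.0)


class DegenerateReferenceError(ValueError):
    """Zero-dose reference reading is missing, zero or non-finite."""


class InvalidFitError(ValueError):
    """Operation requires a converged Hill fit."""


@dataclass(frozen=True)
class ViabilityPlate:
    """Raw readings for one (sample, drug) dose series.

    ``readings`` has one row per dose (aligned with ``doses``) and one
    column per replicate well; missing wells are NaN.  A zero-dose row is
    mandatory — it is the normalization reference, never a fitted point.
    """

    sample_id: str
    drug: str
    doses: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        readings = np.atleast_2d(np.asarray(self.readings, dtype=float))
        if doses.ndim != 1 or readings.shape[0] != doses.size:
            raise ValueError("readings must have one row per dose")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if np.unique(doses).size != doses.size:
            raise ValueError(f"duplicate dose rows in plate {self.sample_id!r}")
        if not np.any(doses == 0):
            raise ValueError(f"plate {self.sample_id!r} has no zero-dose reference row")
        if not np.all(np.isfinite(readings).any(axis=1)):
            raise ValueError("every dose row needs at least one finite reading")
        order = np.argsort(doses)
        object.__setattr__(self, "doses", doses[order])
        object.__setattr__(self, "readings", readings[order])

    @property
    def n_replicates(self) -> int:
        return self.readings.shape[1]


@dataclass(frozen=True)
class HillFit:
    """Fitted (k, m, n) of the modified Hill model plus optimizer status."""

    k: float
    m: float
    n: float
    converged: bool = True
    residual_ss: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.m < 0 or self.n > 0:
            raise ValueError("fit bounds require k >= 0, m >= 0, n <= 0")
        if self.residual_ss < 0:
            raise ValueError("residual_ss must be non-negative")

    def __call__(self, dose):
        return evaluate_hill(self, dose)


@dataclass(frozen=True)
class Ec50Result:
    """EC50 in nM, or not-reached when the curve never crosses R = 0.5.

    Only the absolute definition (R = 0.5 of the untreated reference) is
    implemented; ``relative`` records that and is always False.  A
    not-reached EC50 serializes as the literal string ``NA`` plus a reason,
    never as infinity.
    """

    ec50: float | None
    reason: str | None = None
    relative: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.ec50 is not None and not (math.isfinite(self.ec50) and self.ec50 > 0):
            raise ValueError("a reached EC50 must be finite and positive")

    @property
    def reached(self) -> bool:
        return self.ec50 is not None

    def serialize(self) -> str:
        return f"{self.ec50:.6g}" if self.reached else "NA"


@dataclass(frozen=True)
class ResponderLabel:
    sample_id: str
    ec50: Ec50Result
    responder: bool


def evaluate_hill(fit: HillFit | tuple, dose) -> np.ndarray | float:
    """Evaluate R(D) = m * D^n / (k^n + D^n).

    Written in the equivalent form ``m / (1 + (D/k)^(-n))`` which is
    finite at D = 0 (returning the limit m for n < 0) and stable for
    extreme doses.  n = 0 degenerates to the constant m/2.
    """
    k, m, n = (fit.k, fit.m, fit.n) if isinstance(fit, HillFit) else fit
    d = np.asarray(dose, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.empty_like(d)
    if n == 0:
        out[:] = m / 2.0
    elif k == 0:
        # curvature collapsed to zero: response is 0 for any positive dose
        out[:] = np.where(d > 0, 0.0, m)
    else:
        h = -n  # > 0
        with np.errstate(over="ignore"):
            out = m / (1.0 + (d / k) ** h)
    return float(out[0]) if scalar else out


def normalize_plate(plate: ViabilityPlate) -> tuple[np.ndarray, np.ndarray]:
    """Reference-transform a plate and average over replicates.

    Each replicate column is divided by its own zero-dose reading, then
    the per-dose mean is taken over the finite replicate responses.  The
    mean response at dose 0 is therefore exactly 1.
    """
    zero_row = int(np.flatnonzero(plate.doses == 0)[0])
    ref = plate.readings[zero_row]
    bad = ~np.isfinite(ref) | (ref <= 0)
    if np.all(bad):
        raise DegenerateReferenceError(
            f"plate {plate.sample_id!r}: no usable zero-dose reference reading"
        )
    if np.any(bad):
        which = ", ".join(f"rep{i + 1}" for i in np.flatnonzero(bad))
        raise DegenerateReferenceError(
            f"plate {plate.sample_id!r}: zero or non-finite reference in {which}"
        )
    rel = plate.readings / ref
    with np.errstate(invalid="ignore"):
        mean_response = np.nanmean(rel, axis=1)
    return plate.doses.copy(), mean_response


def fit_hill(doses, mean_response) -> HillFit:
    """Bounded least-squares fit of the modified Hill model.

    Starts at (k, m, n) = (1000, 1, -1) with box bounds k, m in [0, inf)
    and n in (-inf, 0].  Zero-dose points serve only as the normalization
    reference and are excluded here: D^n is singular at D = 0 for n < 0.
    Optimizer failure returns ``converged=False`` rather than raising.
    """
    doses = np.asarray(doses, dtype=float)
    resp = np.asarray(mean_response, dtype=float)
    keep = (doses > 0) & np.isfinite(resp)
    d, y = doses[keep], resp[keep]
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct positive doses to fit")

    def residuals(theta):
        return evaluate_hill(HillFit(*theta), d) - y

    try:
        sol = least_squares(
            residuals,
            x0=HILL_INITIAL_GUESS,
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, 0.0]),
            method="trf",
            xtol=1e-10,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=10_000,
        )
    except Exception:
        return HillFit(*HILL_INITIAL_GUESS, converged=False, residual_ss=np.inf)
    k, m, n = sol.x
    return HillFit(k, m, n, converged=bool(sol.success), residual_ss=float(2 * sol.cost))


def compute_ec50(fit: HillFit) -> Ec50Result:
    """Closed-form EC50 = k * (2m - 1)^(-1/n) from a converged fit.

    When 2m - 1 <= 0 the fitted curve never reaches half of the untreated
    response and the EC50 is not reached; n = 0 (flat curve) likewise has
    no half-maximal crossing.
    """
    if not fit.converged:
        raise InvalidFitError("EC50 requires a converged Hill fit")
    if 2 * fit.m - 1 <= 0:
        return Ec50Result(None, reason="asymptote at or below 0.5")
    if fit.n > -1e-6:
        # steepness numerically zero: the fitted curve is flat and never
        # crosses half-maximal response at any finite dose
        return Ec50Result(None, reason="flat curve (n ~ 0)")
    with np.errstate(over="ignore"):
        ec50 = fit.k * (2 * fit.m - 1) ** (-1.0 / fit.n)
    if not (math.isfinite(ec50) and ec50 > 0):
        return Ec50Result(None, reason="degenerate parameters")
    return Ec50Result(float(ec50))


def ec50_root_find(fit: HillFit, lo: float = 1e-9, hi: float = 1e12) -> float:
    """Numeric root of R(D) = 0.5 by bisection; independent check of the
    closed form (the curve is monotone in D for n < 0)."""
    f = lambda d: evaluate_hill(fit, d) - 0.5
    if f(lo) <= 0 or f(hi) >= 0:
        raise ValueError("R(D) = 0.5 is not bracketed on [lo, hi]")
    return float(brentq(f, lo, hi, xtol=1e-300, rtol=1e-15))


def classify_responder(
    sample_id: str, ec50: Ec50Result, cutoff: float = RESPONDER_CUTOFF_NM
) -> ResponderLabel:
    """Responder iff EC50 is reached and strictly below the cutoff.

    An EC50 exactly at the cutoff classifies as non-responder (the rule is
    stated with strict inequalities on both sides; the boundary is closed
    on the non-responder side here).  Not-reached is always non-responder.
    """
    responder = ec50.reached and ec50.ec50 < cutoff
    return ResponderLabel(sample_id=sample_id, ec50=ec50, responder=bool(responder))
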