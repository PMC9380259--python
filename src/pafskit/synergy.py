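"""Loewe-additivity synergy scoring for two-drug combination grids.

Under Loewe additivity a dose ``a`` of drug A is exchangeable for the
*equivalent dose* of drug B producing the same single-agent response.
With both single agents following the modified Hill model
``R(D) = m D^n / (k^n + D^n)``, setting ``R_a(a) = R_b(b)`` and solving
for ``b`` gives the closed form

    b_hat(a) = [ m_a a^p k_b^q / (k_a^p m_b - m_a a^p + m_b a^p) ]^(1/q)

with (k_a, m_a, p) and (k_b, m_b, q) the two fits' (k, m, n).  The
expected response of the combination (a, b) is then drug B's curve at
the summed B-scale dose,

    R_expected(a, b) = R_b(b + b_hat(a))

and the synergy score is ``S_ab = R_expected - R_measured``: positive
scores mean the combination kills more than additivity predicts
(superadditivity / synergy), negative scores mean antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_response import Ec50Result, HillFit, compute_ec50, evaluate_hill, fit_hill

__all__ = [
    "CombinationGrid",
    "SynergyMatrix",
    "MarginFitError",
    "EquivalentDose",
    "equivalent_dose",
    "expected_response",
    "synergy_matrix",
    "ec50_shift_profile",
]


class MarginFitError(RuntimeError):
    """A single-agent margin of the grid could not be fitted."""


@dataclass(frozen=True)
class CombinationGrid:
    """Mean relative responses on a (doses_a x doses_b) dose grid.

    Both dose lists must include 0 so the single-agent margins are part
    of the grid; ``measured[0, 0]`` (the untreated corner after sorting)
    is 1 within tolerance by construction of the normalization.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        meas = np.asarray(self.measured, dtype=float)
        if meas.shape != (da.size, db.size):
            raise ValueError("measured must be |doses_a| x |doses_b|")
        if 0 not in da or 0 not in db:
            raise ValueError("both dose lists must include 0")
        ia, ib = np.argsort(da), np.argsort(db)
        object.__setattr__(self, "doses_a", da[ia])
        object.__setattr__(self, "doses_b", db[ib])
        object.__setattr__(self, "measured", meas[np.ix_(ia, ib)])


@dataclass(frozen=True)
class SynergyMatrix:
    """Per-dose-pair Loewe scores aligned with the source grid."""

    grid: CombinationGrid
    expected: np.ndarray
    scores: np.ndarray
    clamped: np.ndarray
    fit_a: HillFit
    fit_b: HillFit


@dataclass(frozen=True)
class EquivalentDose:
    """Drug-B dose matching a drug-A response; may be clamped or infinite.

    ``clamped`` is set when drug B cannot reach drug A's response level
    (R_a(a) >= m_b) and the dose was clamped to 0 rather than silently
    extrapolated.  ``dose`` is ``math.inf`` when R_a(a) -> 0, i.e. no
    finite dose of B is equivalent.
    """

    dose: float
    clamped: bool = False

    @property
    def infinite(self) -> bool:
        return math.isinf(self.dose)


def equivalent_dose(fit_a: HillFit, fit_b: HillFit, a: float) -> EquivalentDose:
    """Dose of drug B with the same single-agent response as dose ``a`` of A."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("equivalent_dose requires converged fits")
    if a < 0:
        raise ValueError("dose must be non-negative")
    r = evaluate_hill(fit_a, a)
    mb, kb, q = fit_b.m, fit_b.k, fit_b.n
    if q == 0 or kb == 0:
        raise ValueError("drug b fit is degenerate (n = 0 or k = 0)")
    if r >= mb:
        # drug b cannot reach that response level even at dose 0
        return EquivalentDose(0.0, clamped=True)
    if r <= 0:
        return EquivalentDose(math.inf)
    # b^q = r k_b^q / (m_b - r)  =>  b = k_b (r / (m_b - r))^(1/q)
    b = kb * (r / (mb - r)) ** (1.0 / q)
    return EquivalentDose(float(b))


def expected_response(fit_a: HillFit, fit_b: HillFit, a: float, b: float) -> float:
    """Loewe-expected response of the pair (a, b): R_b(b + b_hat(a)).

    An infinite equivalent dose (drug A has fully suppressed response)
    returns 0, the high-dose limit of drug B's curve for n < 0.
    """
    beq = equivalent_dose(fit_a, fit_b, a)
    if beq.infinite:
        return 0.0
    return float(evaluate_hill(fit_b, b + beq.dose))


def _fit_margin(doses, responses, drug: str) -> HillFit:
    try:
        fit = fit_hill(doses, responses)
    except ValueError as exc:
        raise MarginFitError(f"margin fit failed for drug {drug!r}: {exc}") from exc
    if not fit.converged:
        raise MarginFitError(f"margin fit did not converge for drug {drug!r}")
    return fit


def synergy_matrix(
    grid: CombinationGrid,
    fit_a: HillFit | None = None,
    fit_b: HillFit | None = None,
    symmetrize: bool = False,
) -> SynergyMatrix:
    """Score every dose pair of a grid against Loewe additivity.

    Single-agent Hill fits are estimated from the grid's own margins
    (row b = 0 for drug A, column a = 0 for drug B) unless explicit fits
    are injected.  ``symmetrize`` averages the a->b and b->a transform
    directions; the default is the asymmetric a->b form.
    """
    ja = int(np.flatnonzero(grid.doses_b == 0)[0])
    ia = int(np.flatnonzero(grid.doses_a == 0)[0])
    if fit_a is None:
        fit_a = _fit_margin(grid.doses_a, grid.measured[:, ja], grid.drug_a)
    if fit_b is None:
        fit_b = _fit_margin(grid.doses_b, grid.measured[ia, :], grid.drug_b)

    na, nb = grid.doses_a.size, grid.doses_b.size
    expected = np.empty((na, nb))
    clamped = np.zeros((na, nb), dtype=bool)
    for i, a in enumerate(grid.doses_a):
        beq = equivalent_dose(fit_a, fit_b, a)
        clamped[i, :] = beq.clamped
        for j, b in enumerate(grid.doses_b):
            if beq.infinite:
                expected[i, j] = 0.0
            else:
                expected[i, j] = evaluate_hill(fit_b, b + beq.dose)
    if symmetrize:
        other = np.empty((na, nb))
        for j, b in enumerate(grid.doses_b):
            aeq = equivalent_dose(fit_b, fit_a, b)
            for i, a in enumerate(grid.doses_a):
                if aeq.infinite:
                    other[i, j] = 0.0
                else:
                    other[i, j] = evaluate_hill(fit_a, a + aeq.dose)
        expected = 0.5 * (expected + other)
    scores = expected - grid.measured
    return SynergyMatrix(
        grid=grid, expected=expected, scores=scores, clamped=clamped, fit_a=fit_a, fit_b=fit_b
    )


def ec50_shift_profile(grid: CombinationGrid) -> list[tuple[float, Ec50Result]]:
    """Drug-A EC50 re-fitted at each fixed dose of drug B.

    Each fixed-b slice is re-normalized to its own a = 0 response before
    fitting, so the EC50 measures potency of drug A on top of that
    background dose of B.  A failed or non-converged slice fit yields a
    not-reached EC50 and the profile continues; so does an EC50 that
    falls beyond the tested dose range of drug A (a flat slice fits a
    degenerate curve whose extrapolated crossing is not reportable).
    """
    max_dose_a = float(grid.doses_a.max())
    ia0 = int(np.flatnonzero(grid.doses_a == 0)[0])
    profile: list[tuple[float, Ec50Result]] = []
    for j, b in enumerate(grid.doses_b):
        col = grid.measured[:, j]
        base = col[ia0]
        if not (np.isfinite(base) and base > 0):
            profile.append((float(b), Ec50Result(None, reason="degenerate a=0 response")))
            continue
        try:
            fit = fit_hill(grid.doses_a, col / base)
            ec = (
                compute_ec50(fit)
                if fit.converged
                else Ec50Result(None, reason="slice fit did not converge")
            )
            if ec.reached and ec.ec50 > max_dose_a:
                ec = Ec50Result(None, reason="EC50 beyond tested dose range")
        except ValueError as exc:
            ec = Ec50Result(None, reason=str(exc))
        profile.append((float(b), ec))
    return profile
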