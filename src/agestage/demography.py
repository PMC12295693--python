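"""Population parameters and age-stage expectancy/reproductive-value grids.

Parameters derived from the life-table surfaces:

* net reproductive rate  ``R0 = sum_x l_x m_x``  (offspring per newborn);
* intrinsic rate of increase ``r``, the root of the discrete Euler–Lotka
  equation ``sum_x exp(-r (x+1)) l_x m_x = 1`` with age indexed from 0
  (the +1 offset convention of the age-stage two-sex framework);
* finite rate ``lambda = exp(r)`` (per day);
* mean generation time ``T = ln(R0) / r``.

The age-stage life expectancy ``e_xj`` and reproductive value ``v_xj`` are
computed by backward recursion over the empirical age-stage transition
counts recorded in the survival grid:

    e_xj = 1 + sum_y P(x,j -> x+1,y) e_{x+1,y}
    v_xj = f_xj + exp(-r) sum_y P(x,j -> x+1,y) v_{x+1,y}

where ``P`` are the observed one-day transition fractions (deaths absorb
the deficit).  These recursions reproduce two exact identities used as
self-checks on every analyzed cohort: ``e_{0,1}`` equals the arithmetic
mean lifespan of the cohort, and ``v_{0,1}`` equals ``lambda``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stages as st
from .cohort import Cohort
from .errors import NumericError
from .lifetable import FecundityGrid, LifeTableGrid, compute_fecundity, compute_sxj

__all__ = [
    "DemographicParams",
    "ExpectancyGrid",
    "ReproValueGrid",
    "net_reproductive_rate",
    "net_reproductive_rate_two_sex",
    "intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "life_expectancy",
    "reproductive_value",
    "demographic_params",
    "euler_lotka_residual",
    "solve_euler_lotka",
    "identity_report",
]

#: residual tolerance the Euler–Lotka root must satisfy
RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class DemographicParams:
    """Point estimates of the four population parameters (per-day rates)."""

    R0: float
    r: float
    lam: float
    T: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["R0_offspring", "r_per_day", "lambda_per_day", "T_days"],
                "estimate": [self.R0, self.r, self.lam, self.T],
            }
        )


@dataclass(frozen=True)
class ExpectancyGrid:
    """Remaining expected lifespan (days) per age-stage cell; 0 where empty."""

    exj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        ages, cols = np.nonzero(self.exj)
        return pd.DataFrame(
            {"age": ages, "stage": [st.STAGES[c] for c in cols], "exj": self.exj[ages, cols]}
        )


@dataclass(frozen=True)
class ReproValueGrid:
    """Expected growth-discounted future offspring per age-stage cell."""

    vxj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        ages, cols = np.nonzero(self.vxj)
        return pd.DataFrame(
            {"age": ages, "stage": [st.STAGES[c] for c in cols], "vxj": self.vxj[ages, cols]}
        )


# ---------------------------------------------------------------------------
# scalar parameters


def net_reproductive_rate(fec: FecundityGrid) -> float:
    """R0 = sum of the net maternity schedule l_x m_x."""
    return float(fec.net_maternity.sum())


def net_reproductive_rate_two_sex(F: float, n_female: int, n: int) -> float:
    """Two-sex identity R0 = F * N_f / N.

    ``F`` is mean eggs per female adult (all females), ``n_female`` the
    number of females that emerged and ``n`` the cohort size.  Equals
    :func:`net_reproductive_rate` exactly on any cohort, and lets R0 be
    recovered from published summary statistics alone.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    return F * n_female / n


def euler_lotka_residual(r, net_maternity: np.ndarray):
    """``sum_x exp(-r (x+1)) l_x m_x - 1`` (vectorised over r)."""
    phi = np.asarray(net_maternity, dtype=float)
    x1 = np.arange(1, phi.size + 1, dtype=float)
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    res = np.exp(-np.outer(r_arr, x1)) @ phi - 1.0
    return res if np.ndim(r) else float(res[0])


def solve_euler_lotka(net_maternity: np.ndarray, tol: float = 1e-12) -> float:
    """Solve the Euler–Lotka equation for r by safeguarded bisection.

    The residual is strictly decreasing in r, so the root is unique.  The
    initial bracket [-1, 2] is expanded if needed; bisection runs to the
    requested tolerance on r and a final Newton polish tightens the
    residual to machine level.

    Raises
    ------
    NumericError
        If R0 = 0 (no root) or the root cannot be bracketed.
    """
    phi = np.asarray(net_maternity, dtype=float)
    if phi.sum() <= 0:
        raise NumericError("R0 = 0: intrinsic rate of increase undefined")
    r = _solve_euler_lotka_batch(phi[None, :], tol=tol)[0]
    res = euler_lotka_residual(r, phi)
    if not math.isfinite(r) or abs(res) > RESIDUAL_TOL:
        raise NumericError(f"Euler–Lotka solve failed: r={r}, residual={res}")
    return float(r)


def _solve_euler_lotka_batch(phi: np.ndarray, tol: float = 1e-12, iters: int = 75) -> np.ndarray:
    """Vectorised bisection+Newton over rows of a net-maternity matrix.

    Rows with zero total maternity yield NaN.  Used both for single
    cohorts and for the bootstrap, where each row is one resample.
    """
    B, A = phi.shape
    x1 = np.arange(1, A + 1, dtype=float)
    ok = phi.sum(axis=1) > 0
    lo = np.full(B, -1.0)
    hi = np.full(B, 2.0)

    def res_at(r):
        with np.errstate(over="ignore"):
            return np.einsum("ba,ba->b", np.exp(-r[:, None] * x1[None, :]), phi) - 1.0

    # expand brackets where needed (residual decreasing: want res(lo)>0>res(hi))
    for _ in range(60):
        bad_lo = ok & (res_at(lo) <= 0)
        bad_hi = ok & (res_at(hi) >= 0)
        if not bad_lo.any() and not bad_hi.any():
            break
        lo = np.where(bad_lo, lo * 2 - 1, lo)
        hi = np.where(bad_hi, hi * 2 + 1, hi)
    else:  # pragma: no cover - unreachable for valid schedules
        raise NumericError("Euler–Lotka root could not be bracketed")

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = res_at(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
        if np.all(hi - lo < tol):
            break
    r = 0.5 * (lo + hi)
    # one Newton step to polish (derivative is -sum (x+1) e^{-r(x+1)} phi)
    with np.errstate(over="ignore", invalid="ignore"):
        e = np.exp(-r[:, None] * x1[None, :])
        f = np.einsum("ba,ba->b", e, phi) - 1.0
        df = -np.einsum("ba,a,ba->b", e, x1, phi)
        step = np.where(df != 0, f / df, 0.0)
        r = np.where(np.abs(step) < 1e-6, r - step, r)
    return np.where(ok, r, np.nan)


def intrinsic_rate(fec: FecundityGrid) -> float:
    """Intrinsic rate of increase r (per day) from the maternity schedule."""
    return solve_euler_lotka(fec.net_maternity)


def finite_rate(r: float) -> float:
    """Finite (per-day multiplicative) rate of increase, lambda = e^r."""
    return math.exp(r)


def mean_generation_time(R0: float, r: float) -> float:
    """T = ln(R0)/r; the r -> 0 limit uses the maternity-weighted mean age."""
    if R0 <= 0:
        raise NumericError("R0 <= 0: generation time undefined")
    if r == 0.0:
        if not math.isclose(R0, 1.0, rel_tol=1e-9):
            raise NumericError(f"r = 0 inconsistent with R0 = {R0}")
        return math.nan  # limit depends on the schedule; callers with r=0 use the schedule form
    return math.log(R0) / r


def demographic_params(
    cohort: Cohort,
    grid: LifeTableGrid | None = None,
    fec: FecundityGrid | None = None,
) -> DemographicParams:
    """Compute R0, r, lambda and T for one cohort."""
    grid = grid if grid is not None else compute_sxj(cohort)
    fec = fec if fec is not None else compute_fecundity(cohort, grid)
    R0 = net_reproductive_rate(fec)
    r = intrinsic_rate(fec)
    return DemographicParams(R0=R0, r=r, lam=finite_rate(r), T=mean_generation_time(R0, r))


# ---------------------------------------------------------------------------
# age-stage grids


def life_expectancy(grid: LifeTableGrid) -> ExpectancyGrid:
    """Backward recursion for the remaining expected lifespan e_xj.

    An individual alive in (x, j) lives through day x (counted as one
    day) and then, with the observed transition fractions, continues in
    one of the occupied cells at x+1.
    """
    A, S = grid.sxj.shape
    exj = np.zeros((A, S))
    for x in range(A - 2, -1, -1):
        nxj = grid.counts[x]
        for j in np.nonzero(nxj)[0]:
            cont = grid.transitions[x, j] @ exj[x + 1]
            exj[x, j] = 1.0 + cont / nxj[j]
    # cells occupied on the final day with survivors would need a longer grid;
    # by construction nobody is alive on the last grid day.
    last = A - 1
    for j in np.nonzero(grid.counts[last])[0]:  # pragma: no cover - empty by construction
        exj[last, j] = 1.0
    return ExpectancyGrid(exj=exj)


def reproductive_value(grid: LifeTableGrid, fec: FecundityGrid, r: float) -> ReproValueGrid:
    """Backward recursion for the reproductive value v_xj.

    v_xj accumulates the eggs laid in the cell today (f_xj) plus the
    growth-discounted value of the cells reachable tomorrow.  With the r
    solved from the same cohort, v at the newborn cell equals lambda.
    """
    if not math.isfinite(r):
        raise NumericError("r is not finite; reproductive value undefined")
    A, S = grid.sxj.shape
    disc = math.exp(-r)
    vxj = np.zeros((A, S))
    for x in range(A - 2, -1, -1):
        nxj = grid.counts[x]
        for j in np.nonzero(nxj)[0]:
            cont = grid.transitions[x, j] @ vxj[x + 1]
            vxj[x, j] = fec.fxj[x, j] + disc * cont / nxj[j]
    return ReproValueGrid(vxj=vxj)


# ---------------------------------------------------------------------------
# self-checks


def identity_report(cohort: Cohort) -> dict[str, float]:
    """Evaluate the five internal identities on a cohort and return deltas.

    Keys: ``lambda_vs_exp_r``, ``euler_lotka_residual``, ``egg_conservation``,
    ``e01_vs_mean_lifespan``, ``v01_vs_lambda`` — each the absolute
    discrepancy of an identity that must hold on any analyzable cohort.
    """
    grid = compute_sxj(cohort)
    fec = compute_fecundity(cohort, grid)
    params = demographic_params(cohort, grid, fec)
    exj = life_expectancy(grid).exj
    vxj = reproductive_value(grid, fec, params.r).vxj
    mean_life = float(np.mean([i.end_day for i in cohort.individuals]))
    return {
        "lambda_vs_exp_r": abs(params.lam - math.exp(params.r)),
        "euler_lotka_residual": abs(euler_lotka_residual(params.r, fec.net_maternity)),
        "egg_conservation": abs(fec.net_maternity.sum() * cohort.n - cohort.total_eggs()),
        "e01_vs_mean_lifespan": abs(exj[0, 0] - mean_life),
        "v01_vs_lambda": abs(vxj[0, 0] - params.lam),
    }
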