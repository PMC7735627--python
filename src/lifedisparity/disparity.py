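"""Lifespan disparity (e-dagger), its threshold age, and the
compression/expansion decomposition summarised by the REC.

Life disparity is measured as life expectancy lost due to death,

    e-dagger = int_0^omega d(a) e(a) da,

the average remaining life expectancy at death.  For a life table with
entropy (e-dagger / e0) below one there is a unique threshold age a-dagger:
averting deaths below it *compresses* the age-at-death distribution and
lowers disparity, averting deaths above it *expands* the distribution and
raises disparity.  Splitting the integral at a-dagger,

    e-dagger = ec (compression part, below)  +  ee (expansion part, above),

and the ratio of expansion to compression REC = ee / ec is the headline
summary: it tracks which of the two opposing forces dominates.  DEC = ee - ec
is its additive counterpart.

The threshold age is located through the sensitivity of e-dagger to a
relative mortality reduction at age x,

    g(x) = d(x) * [ e-dagger(x) + e(x) * (H(x) - 1) ],

where e-dagger(x) is the conditional disparity above x.  Since d(x) >= 0 the
sign structure lives in the bracket phi(x) = e-dagger(x) + e(x)(H(x)-1);
a-dagger is phi's unique zero crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousThresholdError,
    InvalidArgumentError,
    NoThresholdError,
    UndefinedValueError,
)
from .grid import AgeGrid
from .lifetable import LifeTable, _L_TINY

__all__ = [
    "SensitivityCurves",
    "DisparityResult",
    "e_dagger",
    "e_dagger_above",
    "sensitivity_curves",
    "threshold_age",
    "decompose",
    "entropy",
]


@dataclass(frozen=True)
class SensitivityCurves:
    """Per-age sensitivity of e-dagger to relative mortality decline.

    Attributes
    ----------
    edag_above : conditional disparity e-dagger(x) in years.
    phi : bracket term e-dagger(x) + e(x)(H(x)-1) in years; its unique zero
        crossing is the threshold age.
    g : d(x)*phi(x); years of e-dagger change per unit of relative mortality
        decline concentrated at age x.
    """

    grid: AgeGrid
    edag_above: np.ndarray
    phi: np.ndarray
    g: np.ndarray


@dataclass(frozen=True)
class DisparityResult:
    """Disparity summary for one mortality schedule.  All ages/years in
    years; ``rec`` and ``entropy`` dimensionless."""

    e0: float
    edag: float
    a_dag: float
    ec: float
    ee: float
    rec: float
    dec: float
    entropy: float

    @classmethod
    def from_components(
        cls,
        ec: float,
        ee: float,
        e0: float = float("nan"),
        a_dag: float = float("nan"),
    ) -> "DisparityResult":
        """Assemble a result from already-known compression/expansion
        components (e.g. published table rows); edag, REC and DEC follow
        from the identities edag = ec + ee, REC = ee/ec, DEC = ee - ec."""
        if ec < 0 or ee < 0:
            raise InvalidArgumentError("components must be non-negative")
        edag = ec + ee
        rec = ee / ec if ec > 0 else float("inf")
        ent = edag / e0 if e0 and e0 > 0 else float("nan")
        return cls(e0=e0, edag=edag, a_dag=a_dag, ec=ec, ee=ee,
                   rec=rec, dec=ee - ec, entropy=ent)

    def summary(self) -> str:
        lines = [
            f"e0 (life expectancy at birth)  {self.e0:10.4f} years",
            f"e-dagger (life disparity)      {self.edag:10.4f} years",
            f"a-dagger (threshold age)       {self.a_dag:10.4f} years",
            f"compression component ec       {self.ec:10.4f} years",
            f"expansion component ee         {self.ee:10.4f} years",
            f"REC = ee/ec                    {self.rec:10.4f}",
            f"DEC = ee-ec                    {self.dec:10.4f} years",
            f"entropy = e-dagger/e0          {self.entropy:10.4f}",
        ]
        return "\n".join(lines)


def e_dagger(lt: LifeTable) -> float:
    """Life disparity e-dagger = int d(a) e(a) da, in years.  The closure
    mass at omega contributes nothing since e(omega) = 0."""
    return lt.integrate_against_deaths(lt.e)


def _edag_above_curve(lt: LifeTable) -> np.ndarray:
    """Conditional disparity e-dagger(x) at every grid age (0 where l=0)."""
    ebar = 0.5 * (lt.e[:-1] + lt.e[1:])
    cell = lt.death_cell_mass * ebar
    upper = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])
    # closure mass at omega carries e(omega)=0: no contribution
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lt.l > _L_TINY, upper / np.maximum(lt.l, _L_TINY), 0.0)
    return out


def e_dagger_above(lt: LifeTable, x: float) -> float:
    """Conditional disparity above age ``x``:
    e-dagger(x) = int_x^omega d e / l(x).  Linear interpolation between grid
    ages; ``x = 0`` recovers :func:`e_dagger` exactly."""
    if not (0.0 <= x <= lt.grid.omega):
        raise InvalidArgumentError(f"age {x} outside [0, {lt.grid.omega}]")
    lx = float(np.interp(x, lt.grid.ages, lt.l))
    if lx <= _L_TINY:
        raise UndefinedValueError(f"e-dagger({x}) undefined: survival is zero")
    if x == 0.0:
        return e_dagger(lt)
    return float(np.interp(x, lt.grid.ages, _edag_above_curve(lt)))


def sensitivity_curves(lt: LifeTable) -> SensitivityCurves:
    """Compute phi and g = d*phi at every grid age."""
    edag_above = _edag_above_curve(lt)
    phi = edag_above + lt.e * (lt.Hcum - 1.0)
    g = lt.d * phi
    return SensitivityCurves(grid=lt.grid, edag_above=edag_above, phi=phi, g=g)


def entropy(lt: LifeTable) -> float:
    """Life-table entropy e-dagger / e0: 1 for a constant hazard, -> 0 for a
    rectangular survival curve."""
    e0 = lt.e0
    if e0 <= 0:
        raise UndefinedValueError("entropy undefined: e0 <= 0")
    return e_dagger(lt) / e0


def _phi_crossings(lt: LifeTable, phi: np.ndarray) -> list[float]:
    """Zero crossings of phi, linearly interpolated, restricted to ages with
    non-negligible survival (the extinct tail is all exact zeros)."""
    ages = lt.grid.ages
    valid = lt.l > 1e-12
    idx = np.nonzero(valid)[0]
    hi = idx[-1] if idx.size else 0
    # exact zeros (the closed-out tail, phi(omega)=0) carry no sign
    # information: crossings are read off consecutive *nonzero* values
    nz = np.nonzero(phi[: hi + 1])[0]
    crossings = []
    for i, j in zip(nz[:-1], nz[1:]):
        a, b = phi[i], phi[j]
        if (a < 0.0) != (b < 0.0):
            t = a / (a - b)
            crossings.append(float(ages[i] + t * (ages[j] - ages[i])))
    return crossings


def threshold_age(lt: LifeTable) -> float:
    """Threshold age a-dagger: the unique zero of phi on (0, omega).

    Raises :class:`NoThresholdError` when entropy >= 1 (no such age exists)
    and :class:`AmbiguousThresholdError` if numerical noise produces several
    sign changes.  A phi that is already non-negative at age 0 (the
    constant-hazard limit, entropy -> 1) returns 0.0.
    """
    ent = entropy(lt)
    if ent >= 1.0:
        raise NoThresholdError(ent)
    curves = sensitivity_curves(lt)
    if curves.phi[0] >= 0.0:
        return 0.0
    crossings = _phi_crossings(lt, curves.phi)
    if len(crossings) == 0:
        raise NoThresholdError(ent)
    if len(crossings) > 1:
        raise AmbiguousThresholdError(crossings)
    return crossings[0]


def decompose(lt: LifeTable) -> DisparityResult:
    """Full disparity summary: e-dagger split at a-dagger into compression
    and expansion, with REC, DEC and entropy.

    The grid cell containing a-dagger is split with ``l`` and ``e`` linearly
    interpolated at a-dagger, which conserves ec + ee = e-dagger to machine
    precision.  ``ec == 0`` (threshold at age 0) yields an infinite REC with
    a warning.
    """
    a_dag = threshold_age(lt)  # propagates no-threshold errors
    ages = lt.grid.ages
    ebar = 0.5 * (lt.e[:-1] + lt.e[1:])
    cell = lt.death_cell_mass * ebar

    if a_dag <= 0.0:
        ec = 0.0
        ee = float(cell.sum())
    elif a_dag >= lt.grid.omega:
        ec = float(cell.sum())
        ee = 0.0
    else:
        i = lt.grid.index_below(a_dag)
        theta = (a_dag - ages[i]) / lt.grid.step
        l_dag = lt.l[i] + theta * (lt.l[i + 1] - lt.l[i])
        e_dag_at = lt.e[i] + theta * (lt.e[i + 1] - lt.e[i])
        lower_split = (lt.l[i] - l_dag) * 0.5 * (lt.e[i] + e_dag_at)
        upper_split = (l_dag - lt.l[i + 1]) * 0.5 * (e_dag_at + lt.e[i + 1])
        ec = float(cell[:i].sum() + lower_split)
        ee = float(upper_split + cell[i + 1:].sum())
    # closure mass at omega: e(omega)=0, contributes to neither part

    edag = ec + ee
    if ec > 0.0:
        rec = ee / ec
    else:
        warnings.warn(
            "compression component is zero (threshold at age 0); REC reported "
            "as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        rec = float("inf")
    e0 = lt.e0
    return DisparityResult(
        e0=e0, edag=edag, a_dag=a_dag, ec=ec, ee=ee,
        rec=rec, dec=ee - ec, entropy=edag / e0,
    )
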