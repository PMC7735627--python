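"""Closed-form hazard families for testing and demonstration.

Four families spanning the whole entropy range, so both the degenerate
(entropy ~ 1, REC -> inf) and well-posed (0 < entropy < 1) regimes are
exercised without any external data:

* ``constant``            mu(x) = c            entropy ~ 1 (exponential)
* ``gompertz``            mu(x) = a e^{bx}     adult senescence, 0 < entropy < 1
* ``gompertz_makeham``    mu(x) = a e^{bx} + c senescence + background
* ``near_rectangular``    gompertz with steep b (>= 0.5): deaths pile up at
                          one age, entropy -> 0

Default parameters are round numbers: c = 0.1; gompertz a = 1e-4, b = 0.1;
makeham c = 1e-3; near-rectangular a = 1e-12, b = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .grid import AgeGrid, make_grid
from .lifetable import HazardSchedule

_FAMILIES = ("constant", "gompertz", "gompertz_makeham", "near_rectangular")

_DEFAULTS = {
    "constant": {"c": 0.1},
    "gompertz": {"a": 1e-4, "b": 0.1},
    "gompertz_makeham": {"a": 1e-4, "b": 0.1, "c": 1e-3},
    "near_rectangular": {"a": 1e-12, "b": 0.5},
}


@dataclass(frozen=True)
class FixtureSpec:
    """A named closed-form hazard family with its rate constants."""

    family: str
    params: dict = field(default_factory=dict)
    grid: AgeGrid = field(default_factory=make_grid)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise InvalidArgumentError(
                f"unknown fixture family {self.family!r}; choose from {_FAMILIES}"
            )
        merged = {**_DEFAULTS[self.family], **self.params}
        if any(v <= 0 for v in merged.values()):
            raise InvalidArgumentError(f"fixture rates must be positive: {merged}")
        if self.family == "near_rectangular" and merged["b"] < 0.5:
            raise InvalidArgumentError(
                "near_rectangular requires b >= 0.5 so deaths concentrate"
            )
        object.__setattr__(self, "params", merged)


def make_fixture(spec: FixtureSpec) -> HazardSchedule:
    """Evaluate the family's hazard on the spec's grid."""
    x = spec.grid.ages
    p = spec.params
    if spec.family == "constant":
        mu = np.full_like(x, p["c"])
    elif spec.family in ("gompertz", "near_rectangular"):
        mu = p["a"] * np.exp(p["b"] * x)
    elif spec.family == "gompertz_makeham":
        mu = p["a"] * np.exp(p["b"] * x) + p["c"]
    else:  # pragma: no cover - guarded in FixtureSpec
        raise InvalidArgumentError(spec.family)
    return HazardSchedule(grid=spec.grid, mu=mu)


def expected_values(spec: FixtureSpec) -> dict:
    """Closed-form reference quantities for families that have them.

    Returns a dict with ``l`` (survival at every grid age) and ``e0``
    (life expectancy at birth on [0, omega]); raises
    :class:`InvalidArgumentError` for families without closed forms.
    """
    x = spec.grid.ages
    omega = spec.grid.omega
    p = spec.params
    if spec.family == "constant":
        c = p["c"]
        return {"l": np.exp(-c * x), "e0": (1.0 - np.exp(-c * omega)) / c}
    if spec.family == "gompertz":
        a, b = p["a"], p["b"]
        l = np.exp(-(a / b) * (np.exp(b * x) - 1.0))
        # e0 by fine closed-form quadrature of l (no elementary antiderivative)
        fine = np.linspace(0.0, omega, 20 * (spec.grid.n - 1) + 1)
        lf = np.exp(-(a / b) * (np.exp(b * fine) - 1.0))
        return {"l": l, "e0": float(np.trapezoid(lf, fine))}
    raise InvalidArgumentError(
        f"family {spec.family!r} has no closed-form reference values"
    )
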