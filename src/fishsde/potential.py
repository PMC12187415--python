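"""Bistable potential landscape for the interindividual distance.

The distance process is modelled as dx = F(x) dt + G(x) dW with a cubic
drift deriving from a tilted double-well potential

    V(x) = -alpha * x - beta * (x - xl)^2 * (x - xh)^2,

so F(x) = -dV/dx. ``xl`` is the well of close-proximity swimming, ``xh``
the well of far-distance exploration; ``beta`` sets the barrier between
them and ``alpha`` tilts the landscape. With this sign convention the
wells at xl and xh are attracting when beta < 0, and a positive alpha
lowers the potential at large x (tilt toward exploration) — the tilt
direction is always reported explicitly rather than inferred from a sign
convention. The diffusion term is the parabola G(x) = b2 x^2 + b1 x + b0,
floored at a small positive value inside the simulator domain since a
fitted parabola can cross zero at the domain edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class NotCubicError(ValueError):
    pass


class MonostableError(ValueError):
    """The cubic drift has no real pair of outer equilibria."""


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the tilted double-well potential.

    alpha : cm/s    tilt (0 = unbiased)
    beta  : cm^-2 s^-1   signed quartic coefficient; wells attract iff < 0
    xl, xh : cm     well locations, xl < xh
    """

    alpha: float
    beta: float
    xl: float
    xh: float

    def __post_init__(self) -> None:
        if not self.xl < self.xh:
            raise ValueError("require xl < xh")


@dataclass(frozen=True)
class DiffusionParams:
    """Parabolic diffusion G(x) = b2 x^2 + b1 x + b0 (cm s^-1/2 at x in cm)."""

    b0: float
    b1: float
    b2: float

    def __call__(self, x):
        return self.b2 * np.square(x) + self.b1 * np.asarray(x) + self.b0

    @property
    def coefficients(self) -> np.ndarray:
        """Ascending-degree coefficient vector (b0, b1, b2)."""
        return np.array([self.b0, self.b1, self.b2])


@dataclass
class PolynomialModel:
    """A polynomial in ascending-degree coefficients c0..c_degree."""

    coefficients: np.ndarray
    target: str = ""  # "drift" or "diffusion"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficients")

    @property
    def degree(self) -> int:
        nz = np.flatnonzero(self.coefficients)
        return int(nz[-1]) if nz.size else 0

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coefficients)


@dataclass
class SDEModel:
    """Simulatable 1-D model dx = F(x) dt + G(x) dW on a bounded domain."""

    drift: PolynomialModel
    diffusion: DiffusionParams
    domain: tuple[float, float] = (0.0, 57.0)
    diffusion_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not self.domain[0] < self.domain[1]:
            raise ValueError("empty domain")

    def F(self, x):
        return self.drift(x)

    def G(self, x):
        """Diffusion, floored at ``diffusion_floor`` to stay positive."""
        return np.maximum(self.diffusion(x), self.diffusion_floor)

    @classmethod
    def from_potential(
        cls,
        params: PotentialParams,
        diffusion: DiffusionParams,
        domain: tuple[float, float] = (0.0, 57.0),
    ) -> "SDEModel":
        return cls(
            drift=PolynomialModel(drift_from_potential(params), target="drift"),
            diffusion=diffusion,
            domain=domain,
        )

    def to_dict(self) -> dict:
        return {
            "drift": self.drift.coefficients.tolist(),
            "diffusion": self.diffusion.coefficients.tolist(),
            "domain": list(self.domain),
            "diffusion_floor": self.diffusion_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SDEModel":
        b0, b1, b2 = d["diffusion"]
        return cls(
            drift=PolynomialModel(np.asarray(d["drift"]), target="drift"),
            diffusion=DiffusionParams(b0=b0, b1=b1, b2=b2),
            domain=tuple(d.get("domain", (0.0, 57.0))),
            diffusion_floor=d.get("diffusion_floor", 1e-3),
        )


def potential_value(p: PotentialParams, x) -> np.ndarray | float:
    """V(x) = -alpha x - beta (x - xl)^2 (x - xh)^2, evaluated literally."""
    x = np.asarray(x, dtype=float)
    v = -p.alpha * x - p.beta * (x - p.xl) ** 2 * (x - p.xh) ** 2
    return float(v) if v.ndim == 0 else v


def drift_from_potential(p: PotentialParams) -> np.ndarray:
    """Cubic drift coefficients (a0, a1, a2, a3) of F = -dV/dx.

    Symbolic expansion:
        a3 = 4 beta
        a2 = -6 beta (xl + xh)
        a1 = 2 beta ((xl + xh)^2 + 2 xl xh)
        a0 = alpha - 2 beta xl xh (xl + xh)
    """
    s, q = p.xl + p.xh, p.xl * p.xh
    return np.array(
        [
            p.alpha - 2.0 * p.beta * q * s,
            2.0 * p.beta * (s * s + 2.0 * q),
            -6.0 * p.beta * s,
            4.0 * p.beta,
        ]
    )


def potential_from_drift(cubic: Sequence[float]) -> PotentialParams:
    """Closed-form inverse of :func:`drift_from_potential`.

    Raises NotCubicError if the leading coefficient vanishes and
    MonostableError if the implied well pair is complex (no bistable
    landscape reproduces the cubic).
    """
    a0, a1, a2, a3 = (float(c) for c in cubic)
    if a3 == 0:
        raise NotCubicError("leading coefficient a3 is zero")
    beta = a3 / 4.0
    s = -a2 / (6.0 * beta)
    q = (a1 / (2.0 * beta) - s * s) / 2.0
    alpha = a0 + 2.0 * beta * q * s
    disc = s * s - 4.0 * q
    if disc < 0:
        raise MonostableError(
            "drift cubic has no real well pair (discriminant < 0)"
        )
    root = math.sqrt(disc)
    xl, xh = (s - root) / 2.0, (s + root) / 2.0
    return PotentialParams(alpha=alpha, beta=beta, xl=xl, xh=xh)


def empirical_potential(
    bin_centres: np.ndarray, mean_drift: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct V(x) = -∫F dx by trapezoidal integration over bins.

    Bin centres must be sorted ascending; the potential is anchored to
    zero at the first bin. Returns (bin_centres, potential values).
    """
    x = np.asarray(bin_centres, dtype=float)
    f = np.asarray(mean_drift, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 bins to integrate")
    if (np.diff(x) <= 0).any():
        raise ValueError("bin centres must be strictly increasing")
    from scipy.integrate import cumulative_trapezoid

    v = -cumulative_trapezoid(f, x, initial=0.0)
    return x, v


def bistability_report(model: SDEModel) -> dict:
    """Locate wells and barrier of a cubic-drift model.

    Wells are the stable equilibria (F = 0, F' < 0), the barrier the
    unstable one. Barrier height is V(barrier) minus V at the shallower
    well; ``tilt_direction`` says which well the potential favours.
    Monostable or non-confining (a3 > 0) models are flagged instead of
    raising.
    """
    coefs = model.drift.coefficients
    if coefs.size < 4 or coefs[3] == 0:
        raise NotCubicError("bistability analysis needs a cubic drift")
    a3 = coefs[3]
    poly = np.polynomial.Polynomial(coefs)
    dpoly = poly.deriv()
    roots = poly.roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    wells = [float(r) for r in real if dpoly(r) < 0]
    unstable = [float(r) for r in real if dpoly(r) > 0]
    report = {
        "wells": wells,
        "barrier_x": unstable[0] if len(unstable) == 1 else None,
        "barrier_height": None,
        "tilt_direction": None,
        "bistable": bool(len(wells) == 2 and len(unstable) == 1),
        "confining": bool(a3 < 0),
    }
    if report["bistable"]:
        # potential from -∫F: integrate the cubic exactly
        vpoly = -poly.integ()
        v_wells = [float(vpoly(w)) for w in wells]
        report["barrier_height"] = float(
            vpoly(report["barrier_x"]) - max(v_wells)
        )
        if abs(v_wells[0] - v_wells[1]) < 1e-12:
            report["tilt_direction"] = "unbiased"
        elif v_wells[0] < v_wells[1]:
            report["tilt_direction"] = "toward_close"  # deeper well at small x
        else:
            report["tilt_direction"] = "toward_far"
    return report
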