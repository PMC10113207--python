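"""Model parameterizations, drift and potential functions, fixed-point analysis.

Two sequential-sampling models of two-alternative decisions are defined:

* the classical drift-diffusion model (DDM), ``dx = nu dt + sigma dW``, with
  absorbing boundaries at ``+B`` (correct) and ``-B`` (error);
* the non-linear drift-diffusion model (nl-DDM),
  ``dx = -k (x + a)(x - z)(x - a) dt + sigma dW``, whose drift derives from a
  double-well potential with stable attractors at ``+a`` (correct) and ``-a``
  (error) and an unstable fixed point at ``z``.

Both models share a uniform starting-point distribution centered at ``x0``
with half-width ``sz`` and a non-decision time ``t_nd`` added to the decision
time.  The noise term is read as increments of a Wiener process: a discrete
step contributes ``drift * dt + sigma * sqrt(dt) * N(0, 1)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

__all__ = [
    "ParameterError",
    "EquivalenceError",
    "NlddmParams",
    "DdmParams",
    "DwmParams",
    "FixedPointSet",
    "nlddm_drift",
    "nlddm_drift_derivative",
    "nlddm_potential",
    "ddm_drift",
    "dwm_potential",
    "dwm_to_nlddm",
    "fixed_points",
    "params_to_dict",
    "params_from_dict",
]


class ParameterError(ValueError):
    """A model parameter set violates its geometric or sign constraints."""


class EquivalenceError(ValueError):
    """The requested model reduction does not exist for these parameters."""


@dataclass(frozen=True)
class NlddmParams:
    """nl-DDM parameter set.

    Parameters
    ----------
    k : float
        Time constant of the cubic drift (1/(s · state²)), > 0.  Larger ``k``
        deepens both wells and speeds decisions.
    a : float
        Attractor magnitude (state units), > 0; the absorbing boundaries sit
        at ``±a``.
    z : float
        Unstable fixed point, strictly inside ``(-a, a)``.  Moving ``z``
        toward ``-a`` deepens the correct (``+a``) well.
    x0, sz : float
        Center and half-width of the uniform starting-point distribution;
        ``[x0 - sz, x0 + sz]`` must lie strictly inside ``(-a, a)``.
    t_nd : float
        Non-decision time in seconds, >= 0.
    sigma : float
        Noise scale (state units per sqrt(s)), > 0.
    """

    k: float
    a: float
    z: float = 0.0
    x0: float = 0.0
    sz: float = 0.0
    t_nd: float = 0.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ParameterError(f"k must be > 0, got {self.k}")
        if not (self.a > 0):
            raise ParameterError(f"a must be > 0, got {self.a}")
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.t_nd < 0:
            raise ParameterError(f"t_nd must be >= 0, got {self.t_nd}")
        if self.sz < 0:
            raise ParameterError(f"sz must be >= 0, got {self.sz}")
        if not (-self.a < self.z < self.a):
            raise ParameterError(
                f"z must lie strictly inside (-a, a); got z={self.z}, a={self.a}"
            )
        if not (-self.a < self.x0 - self.sz and self.x0 + self.sz < self.a):
            raise ParameterError(
                "start support [x0 - sz, x0 + sz] = "
                f"[{self.x0 - self.sz}, {self.x0 + self.sz}] must lie strictly "
                f"inside (-a, a) = ({-self.a}, {self.a})"
            )

    @property
    def boundary(self) -> float:
        return self.a

    def drift(self, x):
        return nlddm_drift(x, self)

    def potential(self, x):
        return nlddm_potential(x, self)

    def with_(self, **kw) -> "NlddmParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DdmParams:
    """Classical DDM parameter set: constant drift ``nu``, boundaries ``±B``."""

    nu: float
    B: float
    x0: float = 0.0
    sz: float = 0.0
    t_nd: float = 0.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if not (self.B > 0):
            raise ParameterError(f"B must be > 0, got {self.B}")
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.t_nd < 0:
            raise ParameterError(f"t_nd must be >= 0, got {self.t_nd}")
        if self.sz < 0:
            raise ParameterError(f"sz must be >= 0, got {self.sz}")
        if not (-self.B < self.x0 - self.sz and self.x0 + self.sz < self.B):
            raise ParameterError(
                "start support [x0 - sz, x0 + sz] = "
                f"[{self.x0 - self.sz}, {self.x0 + self.sz}] must lie strictly "
                f"inside (-B, B) = ({-self.B}, {self.B})"
            )

    @property
    def boundary(self) -> float:
        return self.B

    def drift(self, x=None):
        return ddm_drift(self)

    def with_(self, **kw) -> "DdmParams":
        return replace(self, **kw)


ModelParams = Union[NlddmParams, DdmParams]


@dataclass(frozen=True)
class DwmParams:
    """Double-well model potential ``V(x) = -mu x - alpha x² + x⁴``."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class FixedPointSet:
    """Fixed points of the nl-DDM drift with their stability classification."""

    stable: tuple
    unstable: float
    classification: dict


def nlddm_drift(x, p: NlddmParams):
    """Cubic drift ``-k (x + a)(x - z)(x - a)``, defined for all real x."""
    return -p.k * (x + p.a) * (x - p.z) * (x - p.a)


def nlddm_drift_derivative(x, p: NlddmParams):
    """d(drift)/dx; negative at a fixed point means the point is stable."""
    # d/dx [-k((x - z)(x² - a²))] = -k(3x² - 2zx - a²)
    return -p.k * (3.0 * x * x - 2.0 * p.z * x - p.a * p.a)


def nlddm_potential(x, p: NlddmParams):
    """Double-well potential ``k (x⁴/4 - z x³/3 - a² x²/2 + a² z x)``.

    The drift is ``-dV/dx``.
    """
    a2 = p.a * p.a
    return p.k * (x**4 / 4.0 - p.z * x**3 / 3.0 - a2 * x * x / 2.0 + a2 * p.z * x)


def ddm_drift(p: DdmParams):
    """State-independent drift rate ``nu``."""
    return p.nu


def dwm_potential(x, p: DwmParams):
    """DWM potential ``-mu x - alpha x² + x⁴``."""
    return -p.mu * x - p.alpha * x * x + x**4


def dwm_to_nlddm(p: DwmParams) -> NlddmParams:
    """Map a symmetric DWM onto the equivalent nl-DDM.

    Matching the quartic and quadratic coefficients of the two potentials
    gives ``k = 4`` and ``a² = alpha / 2``.  The reduction only exists in the
    symmetric, input-free case ``mu = 0`` (which pairs with ``z = 0``): a
    nonzero tilt ``mu`` introduces a linear term that the nl-DDM potential
    can only produce together with a cubic term the DWM lacks.
    """
    if p.mu != 0:
        raise EquivalenceError(
            "no symmetric nl-DDM reduction exists for mu != 0 "
            f"(got mu={p.mu}); the equivalence holds only at mu=0, z=0"
        )
    return NlddmParams(k=4.0, a=math.sqrt(p.alpha / 2.0), z=0.0)


def fixed_points(p: NlddmParams) -> FixedPointSet:
    """Roots of the cubic drift with stability from the drift derivative."""
    pts = {-p.a: "stable", p.a: "stable", p.z: "unstable"}
    classification = {}
    for x in pts:
        slope = nlddm_drift_derivative(x, p)
        classification[x] = "stable" if slope < 0 else "unstable"
    return FixedPointSet(stable=(-p.a, p.a), unstable=p.z, classification=classification)


# -- flat key/value serialization ------------------------------------------

_MODEL_TAGS = {"nlddm": NlddmParams, "ddm": DdmParams, "dwm": DwmParams}


def params_to_dict(p) -> dict:
    """Serialize a parameter set to a flat dict with a ``model`` tag."""
    if isinstance(p, NlddmParams):
        tag = "nlddm"
    elif isinstance(p, DdmParams):
        tag = "ddm"
    elif isinstance(p, DwmParams):
        tag = "dwm"
    else:
        raise TypeError(f"not a parameter set: {type(p)!r}")
    d = {"model": tag}
    for name in p.__dataclass_fields__:
        d[name] = float(getattr(p, name))
    return d


def params_from_dict(d: dict):
    """Inverse of :func:`params_to_dict`; validation errors propagate."""
    d = dict(d)
    try:
        tag = d.pop("model")
    except KeyError:
        raise ParameterError("parameter dict is missing the 'model' tag") from None
    try:
        cls = _MODEL_TAGS[tag]
    except KeyError:
        raise ParameterError(f"unknown model tag {tag!r}") from None
    fields = set(cls.__dataclass_fields__)
    extra = set(d) - fields
    if extra:
        raise ParameterError(f"unknown fields for model {tag!r}: {sorted(extra)}")
    return cls(**{k: float(v) for k, v in d.items()})
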