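"""Closed-form IVIM and T2-IVIM signal equations.

The intravoxel incoherent motion (IVIM) model describes diffusion-weighted
signal decay as a mixture of a fast, flow-like pseudo-diffusion compartment
(volume fraction ``f``, coefficient ``D*``) and ordinary tissue water
diffusion (fraction ``1 - f``, coefficient ``D``):

    S(b) = S0 * [ f exp(-b D*) + (1 - f) exp(-b D) ]

The extended T2-IVIM model additionally assigns each compartment its own
transverse relaxation time, so that the echo time TE modulates the apparent
compartment weights:

    S(b, TE) = S0 * [ f exp(-b D*) exp(-TE/T2p)
                      + (1 - f) exp(-b D) exp(-TE/T2t) ]

Because blood T2 (``T2p``) typically exceeds tissue T2 (``T2t``), a
conventional single-TE IVIM fit reports an inflated *apparent* fraction

    f_app(TE) = f e^{-TE/T2p} / [ f e^{-TE/T2p} + (1-f) e^{-TE/T2t} ]

which equals the true ``f`` only at TE = 0 or when the two T2s coincide.

Units (enforced, never auto-detected): b in s mm^-2, D and D* in mm^2 s^-1,
TE and T2 in ms.  Signals are evaluated in linear intensity space.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "IVIMParams",
    "T2IVIMParams",
    "ivim_signal",
    "t2ivim_signal",
    "apparent_fraction",
]


@dataclass
class IVIMParams:
    """Bi-exponential IVIM parameter vector.

    Attributes
    ----------
    S0 : float
        Signal scale at b = 0 (arbitrary units, > 0).  Any overall T2
        weighting of a single-TE acquisition is absorbed here.
    f : float
        Pseudo-diffusion volume fraction, in [0, 1].
    D : float
        True (tissue) diffusion coefficient, mm^2 s^-1, > 0.
    Dstar : float
        Pseudo-diffusion coefficient, mm^2 s^-1; physically D* >> D.
    """

    S0: float
    f: float
    D: float
    Dstar: float

    def validate(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be positive, got {self.S0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not self.Dstar > self.D:
            raise ValueError(
                f"Dstar ({self.Dstar}) must exceed D ({self.D})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.f, self.D, self.Dstar], dtype=float)

    @classmethod
    def param_names(cls) -> list[str]:
        return [fld.name for fld in fields(cls)]


@dataclass
class T2IVIMParams:
    """Extended T2-IVIM parameter vector.

    ``S0`` here is independent of both diffusion and T2 weighting; ``T2p``
    and ``T2t`` are the transverse relaxation times (ms) of the
    pseudo-diffusion and true-diffusion compartments.
    """

    S0: float
    f: float
    D: float
    Dstar: float
    T2p: float
    T2t: float

    def validate(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be positive, got {self.S0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not self.Dstar > self.D:
            raise ValueError(
                f"Dstar ({self.Dstar}) must exceed D ({self.D})"
            )
        if not self.T2p > 0:
            raise ValueError(f"T2p must be positive, got {self.T2p}")
        if not self.T2t > 0:
            raise ValueError(f"T2t must be positive, got {self.T2t}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.S0, self.f, self.D, self.Dstar, self.T2p, self.T2t],
            dtype=float,
        )

    @classmethod
    def param_names(cls) -> list[str]:
        return [fld.name for fld in fields(cls)]


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Evaluate the bi-exponential IVIM signal S(b).

    Parameters
    ----------
    params : IVIMParams
    b : float or array-like
        Diffusion weighting, s mm^-2, >= 0.

    Returns
    -------
    Signal intensity with the same shape as ``b``; equals ``S0`` at b = 0
    and decreases monotonically with b.
    """
    barr = _check_nonnegative("b", b)
    s = params.S0 * (
        params.f * np.exp(-barr * params.Dstar)
        + (1.0 - params.f) * np.exp(-barr * params.D)
    )
    return s if isinstance(s, np.ndarray) and np.ndim(b) else float(s)


def t2ivim_signal(params: T2IVIMParams, b, TE) -> np.ndarray | float:
    """Evaluate the extended T2-IVIM signal S(b, TE).

    ``b`` (s mm^-2) and ``TE`` (ms) broadcast against each other; both must
    be non-negative.  With T2p = T2t = T2 this reduces exactly to
    ``exp(-TE/T2) * ivim_signal``.
    """
    barr = _check_nonnegative("b", b)
    tearr = _check_nonnegative("TE", TE)
    s = params.S0 * (
        params.f * np.exp(-barr * params.Dstar) * np.exp(-tearr / params.T2p)
        + (1.0 - params.f)
        * np.exp(-barr * params.D)
        * np.exp(-tearr / params.T2t)
    )
    if np.ndim(b) or np.ndim(TE):
        return s
    return float(s)


def apparent_fraction(f, T2p, T2t, TE) -> np.ndarray | float:
    """Pseudo-diffusion fraction a single-TE IVIM fit would report.

    Given true fraction ``f`` and compartment relaxation times, the
    differential T2 weighting at echo time ``TE`` re-scales the two
    b-dependent exponentials, so a conventional IVIM fit returns

        f_app = f e^{-TE/T2p} / [ f e^{-TE/T2p} + (1-f) e^{-TE/T2t} ]

    f_app equals ``f`` at TE = 0 and for all TE when T2p = T2t; it is
    strictly increasing in TE when T2p > T2t and 0 < f < 1.

    The degenerate fractions f = 0 and f = 1 are returned unchanged
    (short-circuit; avoids 0/0).
    """
    farr = np.asarray(f, dtype=float)
    if np.any((farr < 0) | (farr > 1)):
        raise ValueError("f must lie in [0, 1]")
    if not (np.all(np.asarray(T2p) > 0) and np.all(np.asarray(T2t) > 0)):
        raise ValueError("T2p and T2t must be positive")
    tearr = _check_nonnegative("TE", TE)

    wp = farr * np.exp(-tearr / np.asarray(T2p, dtype=float))
    wt = (1.0 - farr) * np.exp(-tearr / np.asarray(T2t, dtype=float))
    denom = wp + wt
    # f in {0,1} gives denom equal to the surviving weight; the ratio is
    # exact there, but guard anyway for f=1 with huge TE/T2p underflow.
    with np.errstate(invalid="ignore"):
        fapp = np.where(denom > 0, wp / np.where(denom > 0, denom, 1.0), farr)
    out = np.where((farr == 0.0) | (farr == 1.0), farr, fapp)
    return out if np.ndim(out) else float(out)
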