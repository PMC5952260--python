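"""Synthetic liver-like DWI phantoms with known ground truth.

The generator emulates a multi-b/multi-TE liver acquisition: every voxel
carries a full T2-IVIM parameter set (background parenchyma, optionally
with smooth spatial variation, plus vessel-like regions of high
pseudo-diffusion fraction), the forward model produces the noise-free
signal for each scheme row, and Rician noise (magnitude of two independent
Gaussian channels) is added at a configurable SNR.  Repeats are averaged in
the magnitude domain, as repeated magnitude images are in practice.

SNR is defined as S0 / sigma, i.e. relative to the diffusion- and T2-free
scaling term, so the realized image SNR at (b = 0, minimum TE) is lower by
the compartmental T2 weighting.  ``SNR = inf`` produces exact model values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import AcquisitionScheme
from .fitting import SignalSeries
from .models import T2IVIMParams, t2ivim_signal

logger = logging.getLogger(__name__)

__all__ = [
    "VesselRegion",
    "PhantomSpec",
    "PhantomResult",
    "simulate_series",
    "simulate_phantom",
]

# liver-parenchyma-like defaults: moderate perfusion fraction, tissue T2
# ~42 ms, blood-pool T2 ~78 ms
DEFAULT_BACKGROUND = T2IVIMParams(
    S0=100.0, f=0.18, D=1.07e-3, Dstar=0.15, T2p=77.6, T2t=42.1
)
DEFAULT_VESSEL = replace(DEFAULT_BACKGROUND, f=0.6)


@dataclass(frozen=True)
class VesselRegion:
    """A vessel-like structure: a geometry plus parameter overrides.

    ``kind`` is ``"box"`` (axis-aligned, ``extent`` = (x0, x1, y0, y1,
    z0, z1), half-open) or ``"disk"`` (``extent`` = (cx, cy, radius),
    spanning all z).  ``params`` fully replaces the background parameters
    inside the geometry.
    """

    kind: str
    extent: tuple
    params: T2IVIMParams = field(
        default_factory=lambda: replace(DEFAULT_VESSEL)
    )

    def mask(self, dims: tuple[int, int, int]) -> np.ndarray:
        nx, ny, nz = dims
        m = np.zeros(dims, dtype=bool)
        if self.kind == "box":
            x0, x1, y0, y1, z0, z1 = self.extent
            m[x0:x1, y0:y1, z0:z1] = True
        elif self.kind == "disk":
            cx, cy, r = self.extent
            xx, yy = np.meshgrid(
                np.arange(nx), np.arange(ny), indexing="ij"
            )
            m[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = True
        else:
            raise ValueError(f"unknown vessel geometry kind '{self.kind}'")
        if not m.any():
            raise ValueError("vessel region lies outside the grid")
        return m


@dataclass
class PhantomSpec:
    """Geometry, parameter fields, noise level and seed for a phantom."""

    dims: tuple[int, int, int] = (32, 32, 1)
    background: T2IVIMParams = field(
        default_factory=lambda: replace(DEFAULT_BACKGROUND)
    )
    vessels: list[VesselRegion] = field(default_factory=list)
    SNR: float = 50.0
    seed: int = 0
    f_gradient: float = 0.0   # linear f drift across x, total span

    def __post_init__(self) -> None:
        if not self.SNR > 0:
            raise ValueError("SNR must be positive (use np.inf for noiseless)")
        self.background.validate()
        for v in self.vessels:
            v.params.validate()


@dataclass
class PhantomResult:
    volume: np.ndarray                 # (x, y, z, frames)
    truth: dict[str, np.ndarray]       # per-parameter ground-truth maps
    mask: np.ndarray                   # all-True foreground mask
    scheme: AcquisitionScheme


def _rician(rng: np.random.Generator, mean: np.ndarray, sigma: float,
            size) -> np.ndarray:
    """Magnitude of a complex signal with Gaussian channel noise."""
    re = mean + rng.normal(0.0, sigma, size)
    im = rng.normal(0.0, sigma, size)
    return np.sqrt(re**2 + im**2)


def simulate_series(
    params: T2IVIMParams,
    scheme: AcquisitionScheme,
    SNR: float = np.inf,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> SignalSeries:
    """Simulate one ROI/voxel series on a scheme.

    Per scheme entry, ``n_averages`` Rician samples are drawn around the
    noise-free model value with ``sigma = S0 / SNR`` and averaged in the
    magnitude domain.  ``SNR = inf`` returns exact model values.  Output is
    deterministic for a fixed seed.
    """
    if not SNR > 0:
        raise ValueError("SNR must be positive (use np.inf for noiseless)")
    params.validate()
    clean = t2ivim_signal(params, scheme.b, scheme.TE)
    clean = np.atleast_1d(np.asarray(clean, dtype=float))
    if np.isinf(SNR):
        return SignalSeries(scheme, clean)
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = params.S0 / SNR
    out = np.empty(len(scheme))
    for i, (mean, nav) in enumerate(zip(clean, scheme.n_averages)):
        out[i] = _rician(rng, mean, sigma, nav).mean()
    return SignalSeries(scheme, out)


def simulate_phantom(
    spec: PhantomSpec, scheme: AcquisitionScheme
) -> PhantomResult:
    """Build a 4-D phantom volume plus ground-truth maps.

    Frame order equals scheme row order; spatial arrays are indexed
    (x, y, z).  Overlapping vessel regions resolve last-writer-wins (a log
    message records it).  The noise draw for each voxel is an independent
    stream derived from the spec seed, so adding a vessel does not perturb
    the background noise.
    """
    dims = tuple(spec.dims)
    names = T2IVIMParams.param_names()

    truth = {n: np.full(dims, getattr(spec.background, n), dtype=float)
             for n in names}
    if spec.f_gradient:
        ramp = np.linspace(-0.5, 0.5, dims[0]) * spec.f_gradient
        truth["f"] += ramp[:, None, None]
        truth["f"] = np.clip(truth["f"], 0.0, 1.0)

    claimed = np.zeros(dims, dtype=bool)
    for v in spec.vessels:
        m = v.mask(dims)
        if (claimed & m).any():
            logger.info("overlapping vessel regions: last writer wins")
        claimed |= m
        for n in names:
            truth[n][m] = getattr(v.params, n)

    nx, ny, nz = dims
    volume = np.empty(dims + (len(scheme),), dtype=float)
    master = np.random.default_rng(spec.seed)
    # one child stream per voxel, order-stable
    streams = master.spawn(nx * ny * nz)
    vi = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = T2IVIMParams(**{n: float(truth[n][i, j, k])
                                    for n in names})
                series = simulate_series(
                    p, scheme, SNR=spec.SNR, rng=streams[vi]
                )
                volume[i, j, k, :] = series.signal
                vi += 1
    mask = np.ones(dims, dtype=bool)
    return PhantomResult(volume=volume, truth=truth, mask=mask, scheme=scheme)
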