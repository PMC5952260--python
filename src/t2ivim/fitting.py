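"""Bounded nonlinear least-squares estimation of IVIM and T2-IVIM parameters.

Fitting follows the segmented-initialization strategy that is standard for
liver IVIM: a mono-exponential log-linear fit to the high-b points
(b > 150 s mm^-2 by default) yields D; back-projecting that fit to b = 0
gives the excess signal attributable to the pseudo-diffusion compartment and
hence an initial f.  For the T2-IVIM model a further log-linear fit of the
multi-TE data at b = 50 s mm^-2 (where the flow component is essentially
gone) seeds the tissue relaxation time T2t.

The refinement stage is a trust-region-reflective least squares
(:func:`scipy.optimize.least_squares`) with box bounds; the D and D* boxes
are disjoint (D <= 5e-3 <= D*), which enforces D* > D and removes
label-switching between the two exponentials.  Signals are normalized by
their maximum before fitting and S0 rescaled afterwards, purely for
conditioning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .acquisition import AcquisitionScheme
from .models import (
    IVIMParams,
    T2IVIMParams,
    apparent_fraction,
    ivim_signal,
    t2ivim_signal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignalSeries",
    "FitConfig",
    "FitResult",
    "ParameterMaps",
    "FitError",
    "segmented_init_ivim",
    "init_t2t",
    "fit_ivim",
    "fit_t2ivim",
    "fit_voxelwise",
    "read_roi_csv",
    "write_roi_csv",
]


class FitError(ValueError):
    """Raised when a series violates a fitting precondition."""


@dataclass
class SignalSeries:
    """Measured (or simulated) intensity per scheme entry, one ROI/voxel."""

    scheme: AcquisitionScheme
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (len(self.scheme),):
            raise ValueError(
                f"signal length {self.signal.shape} does not match scheme "
                f"length {len(self.scheme)}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal intensities must be non-negative")

    def at_TE(self, TE: float) -> "SignalSeries":
        mask = np.isclose(self.scheme.TE, TE)
        return SignalSeries(self.scheme.subset(mask), self.signal[mask])

    def subset(self, mask) -> "SignalSeries":
        mask = np.asarray(mask, dtype=bool)
        return SignalSeries(self.scheme.subset(mask), self.signal[mask])


@dataclass
class FitConfig:
    """Bounds, tolerances and initialization knobs for both models.

    Units follow the package convention (b s mm^-2, D mm^2 s^-1, T2 ms).
    The D/D* boxes are disjoint so the fast and slow exponentials cannot
    swap roles.
    """

    f_bounds: tuple[float, float] = (0.0, 1.0)
    D_bounds: tuple[float, float] = (1e-5, 5e-3)
    Dstar_bounds: tuple[float, float] = (5e-3, 0.5)
    T2_bounds: tuple[float, float] = (10.0, 1000.0)
    S0_max_factor: float = 10.0       # S0 upper bound = factor * max signal
    b_threshold: float = 150.0        # segmented-init high-b cutoff
    b_ref: float = 50.0               # b used for the T2t seed
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_iter: int = 500
    n_starts: int = 1                 # extra seeded restarts with jitter
    seed: int = 0                     # jitter RNG seed

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        kwargs = {}
        for fld in cls.__dataclass_fields__:
            if fld in d:
                v = d[fld]
                kwargs[fld] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class FitResult:
    """Parameter estimates plus diagnostics for one series."""

    params: IVIMParams | T2IVIMParams
    std_errors: dict[str, float]
    fDstar: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    cost: float

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        """Normal-theory 95% intervals (estimate +/- 1.96 SE)."""
        out = {}
        for name, se in self.std_errors.items():
            est = getattr(self.params, name)
            out[name] = (est - 1.96 * se, est + 1.96 * se)
        return out


# --- segmented initialization ---------------------------------------------


def _loglinear(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line through (x, log y); returns (slope, intercept)."""
    coeffs = np.polyfit(x, np.log(y), 1)
    return float(coeffs[0]), float(coeffs[1])


def segmented_init_ivim(
    series: SignalSeries, b_threshold: float = 150.0
) -> IVIMParams:
    """Two-step start-point estimate for the IVIM fit.

    A mono-exponential is fitted (log-linearly) to points with
    b > ``b_threshold``, giving D and, back-projected to b = 0, the
    tissue-only intercept.  The excess of the measured minimum-b signal over
    that intercept, as a fraction, seeds f (clamped to [0.01, 0.95]).  D*
    has no data-driven seed and starts at 10 x D.
    """
    b = series.scheme.b
    s = series.signal
    high = b > b_threshold
    if high.sum() < 2:
        raise FitError(
            f"need >= 2 points with b > {b_threshold} for segmented "
            f"initialization; found {int(high.sum())}"
        )
    if np.any(s[high] <= 0):
        raise FitError("non-positive signal among high-b points")
    slope, intercept = _loglinear(b[high], s[high])
    D = max(-slope, 1e-6)
    s_int = float(np.exp(intercept))

    bmin = b.min()
    s0 = float(np.mean(s[b == bmin]))
    if s0 <= 0:
        raise FitError("non-positive signal at minimum b")
    f = float(np.clip((s0 - s_int) / s0, 0.01, 0.95))
    return IVIMParams(S0=s0, f=f, D=D, Dstar=10.0 * D)


def init_t2t(series: SignalSeries, b_ref: float = 50.0) -> float:
    """Seed the tissue T2 from the TE decay of the signal at b = ``b_ref``.

    At moderate b the flow compartment is largely suppressed, so the signal
    across TEs decays approximately as exp(-TE/T2t).  Returns the
    log-linear estimate clamped to [10, 1000] ms.
    """
    mask = np.isclose(series.scheme.b, b_ref)
    tes = series.scheme.TE[mask]
    sig = series.signal[mask]
    if len(np.unique(tes)) < 2:
        raise FitError(
            f"need >= 2 distinct TEs at b = {b_ref} for the T2t seed; "
            "choose another b_ref"
        )
    if np.any(sig <= 0):
        raise FitError(f"non-positive signal at b = {b_ref}")
    slope, _ = _loglinear(tes, sig)
    t2t = -1.0 / slope if slope < 0 else 1000.0
    return float(np.clip(t2t, 10.0, 1000.0))


# --- bounded least squares -------------------------------------------------


def _run_ls(residual_fn, x0, bounds, config: FitConfig):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return least_squares(
            residual_fn,
            x0,
            bounds=bounds,
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=config.gtol,
            max_nfev=config.max_iter * len(x0),
        )


def _std_errors(res, n_points: int, names: list[str]) -> dict[str, float]:
    """Asymptotic SEs from the Jacobian: diag( (J'J)^-1 * RSS/(n-p) )."""
    n_par = res.x.size
    dof = max(n_points - n_par, 1)
    rss = float(2.0 * res.cost)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(jtj) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        se = np.full(n_par, np.nan)
    return dict(zip(names, se))


def _multistart(residual_fn, x0, bounds, config: FitConfig):
    """Run the bounded solver from x0 plus seeded jittered restarts."""
    best = _run_ls(residual_fn, x0, bounds, config)
    if config.n_starts > 1:
        rng = np.random.default_rng(config.seed)
        lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
        for _ in range(config.n_starts - 1):
            jitter = x0 * rng.uniform(0.5, 2.0, size=x0.size)
            xj = np.clip(jitter, lo + 1e-12, hi - 1e-12)
            trial = _run_ls(residual_fn, xj, bounds, config)
            if trial.cost < best.cost:
                best = trial
    return best


def fit_ivim(series: SignalSeries, config: FitConfig | None = None) -> FitResult:
    """Fit the bi-exponential IVIM model to a single-TE series.

    The series must contain exactly one TE (filter with
    :meth:`SignalSeries.at_TE` first) and at least four distinct b-values.
    Non-convergence is flagged on the result, never raised.
    """
    config = config or FitConfig()
    if len(series.scheme.unique_TEs()) != 1:
        raise FitError(
            "fit_ivim requires a single-TE series; filter with at_TE() "
            f"(found TEs {series.scheme.unique_TEs().tolist()})"
        )
    if len(series.scheme.unique_bs()) < 4:
        raise FitError("fit_ivim requires >= 4 distinct b-values")

    scale = float(series.signal.max())
    if scale <= 0:
        raise FitError("all-zero signal series")
    s = series.signal / scale
    b = series.scheme.b

    try:
        init = segmented_init_ivim(
            SignalSeries(series.scheme, s), config.b_threshold
        )
    except FitError:
        # degenerate data (e.g. flat signal): fall back to a generic start
        init = IVIMParams(S0=float(s.max()), f=0.1, D=1e-3, Dstar=1e-2)

    lo = [1e-12, config.f_bounds[0], config.D_bounds[0], config.Dstar_bounds[0]]
    hi = [
        config.S0_max_factor * float(s.max()),
        config.f_bounds[1],
        config.D_bounds[1],
        config.Dstar_bounds[1],
    ]
    x0 = np.clip(init.as_array(), np.array(lo) + 1e-12, np.array(hi) - 1e-12)

    def resid(x):
        S0, f, D, Ds = x
        return S0 * (f * np.exp(-b * Ds) + (1 - f) * np.exp(-b * D)) - s

    res = _multistart(resid, x0, (lo, hi), config)
    params = IVIMParams(
        S0=res.x[0] * scale, f=res.x[1], D=res.x[2], Dstar=res.x[3]
    )
    names = IVIMParams.param_names()
    se = _std_errors(res, len(s), names)
    se["S0"] *= scale
    return FitResult(
        params=params,
        std_errors=se,
        fDstar=params.f * params.Dstar,
        residuals=res.fun * scale,
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        cost=float(res.cost) * scale**2,
    )


def fit_t2ivim(series: SignalSeries, config: FitConfig | None = None) -> FitResult:
    """Fit the six-parameter T2-IVIM model to a multi-TE series.

    Requires >= 2 distinct TEs and >= 4 distinct b-values at the minimum
    TE.  Initialization: segmented IVIM start on the minimum-TE subset plus
    the b = 50 T2t seed; T2p starts at twice the T2t seed.
    """
    config = config or FitConfig()
    tes = series.scheme.unique_TEs()
    if len(tes) < 2:
        raise FitError(
            f"fit_t2ivim requires >= 2 distinct TEs (found {len(tes)}); "
            "use fit_ivim for single-TE data"
        )
    min_te_sub = series.at_TE(tes.min())
    if len(min_te_sub.scheme.unique_bs()) < 4:
        raise FitError(
            "fit_t2ivim requires >= 4 distinct b-values at the minimum TE"
        )

    scale = float(series.signal.max())
    if scale <= 0:
        raise FitError("all-zero signal series")
    s = series.signal / scale
    b = series.scheme.b
    te = series.scheme.TE

    norm_series = SignalSeries(series.scheme, s)
    try:
        init_ivim = segmented_init_ivim(
            norm_series.at_TE(tes.min()), config.b_threshold
        )
    except FitError:
        init_ivim = IVIMParams(S0=float(s.max()), f=0.1, D=1e-3, Dstar=1e-2)
    try:
        t2t0 = init_t2t(norm_series, config.b_ref)
    except FitError:
        t2t0 = 50.0
    t2p0 = float(np.clip(2.0 * t2t0, *config.T2_bounds))

    # undo the min-TE T2 weighting baked into the single-TE S0 estimate
    w = init_ivim.f * np.exp(-tes.min() / t2p0) + (
        1 - init_ivim.f
    ) * np.exp(-tes.min() / t2t0)
    s0_0 = init_ivim.S0 / max(w, 1e-6)

    lo = [
        1e-12,
        config.f_bounds[0],
        config.D_bounds[0],
        config.Dstar_bounds[0],
        config.T2_bounds[0],
        config.T2_bounds[0],
    ]
    hi = [
        config.S0_max_factor * float(s.max()) * 10.0,  # S0 precedes T2 decay
        config.f_bounds[1],
        config.D_bounds[1],
        config.Dstar_bounds[1],
        config.T2_bounds[1],
        config.T2_bounds[1],
    ]
    x0 = np.clip(
        np.array([s0_0, init_ivim.f, init_ivim.D, init_ivim.Dstar, t2p0, t2t0]),
        np.array(lo) + 1e-12,
        np.array(hi) - 1e-12,
    )

    def resid(x):
        S0, f, D, Ds, T2p, T2t = x
        model = S0 * (
            f * np.exp(-b * Ds) * np.exp(-te / T2p)
            + (1 - f) * np.exp(-b * D) * np.exp(-te / T2t)
        )
        return model - s

    res = _multistart(resid, x0, (lo, hi), config)
    params = T2IVIMParams(
        S0=res.x[0] * scale,
        f=res.x[1],
        D=res.x[2],
        Dstar=res.x[3],
        T2p=res.x[4],
        T2t=res.x[5],
    )
    names = T2IVIMParams.param_names()
    se = _std_errors(res, len(s), names)
    se["S0"] *= scale
    return FitResult(
        params=params,
        std_errors=se,
        fDstar=params.f * params.Dstar,
        residuals=res.fun * scale,
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        cost=float(res.cost) * scale**2,
    )


# --- voxel-wise maps -------------------------------------------------------


@dataclass
class ParameterMaps:
    """Per-voxel parameter volumes from voxel-wise fitting.

    ``maps`` holds one 3-D float array per parameter (NaN outside the mask
    or where the fit failed) plus ``fDstar`` and, for the T2-IVIM model, an
    ``f_apparent`` map evaluated at a reference TE.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    model: str
    n_failed: int = 0
    n_fitted: int = 0
    config: FitConfig = field(default_factory=FitConfig)


def fit_voxelwise(
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    model: str = "t2ivim",
    config: FitConfig | None = None,
    f_apparent_TE: float | None = None,
) -> ParameterMaps:
    """Fit every masked voxel of a 4-D volume and assemble parameter maps.

    ``volume`` is (x, y, z, frames) with frame order equal to scheme row
    order.  Voxels whose fit raises or fails to converge are recorded as
    NaN and counted; the map generation never aborts.  For the T2-IVIM
    model an apparent-fraction map at ``f_apparent_TE`` (default: minimum
    scheme TE) is included.
    """
    config = config or FitConfig()
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, frames)")
    if volume.shape[3] != len(scheme):
        raise ValueError(
            f"volume has {volume.shape[3]} frames but scheme has "
            f"{len(scheme)} entries"
        )
    spatial = volume.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != spatial:
        raise ValueError(
            f"mask shape {mask.shape} does not match spatial dims {spatial}"
        )
    if model not in ("ivim", "t2ivim"):
        raise ValueError("model must be 'ivim' or 't2ivim'")

    if model == "ivim":
        names = IVIMParams.param_names()
        fitter = fit_ivim
    else:
        names = T2IVIMParams.param_names()
        fitter = fit_t2ivim

    map_names = list(names) + ["fDstar"]
    if model == "t2ivim":
        map_names.append("f_apparent")
        if f_apparent_TE is None:
            f_apparent_TE = float(scheme.unique_TEs().min())

    maps = {n: np.full(spatial, np.nan, dtype=float) for n in map_names}
    n_failed = 0
    idx = np.argwhere(mask)
    if idx.size == 0:
        logger.warning("empty mask: no voxels fitted")
    for (i, j, k) in idx:
        sig = volume[i, j, k, :]
        try:
            series = SignalSeries(scheme, sig)
            result = fitter(series, config)
        except (FitError, ValueError):
            n_failed += 1
            continue
        if not result.converged:
            n_failed += 1
        p = result.params
        for n in names:
            maps[n][i, j, k] = getattr(p, n)
        maps["fDstar"][i, j, k] = result.fDstar
        if model == "t2ivim":
            maps["f_apparent"][i, j, k] = apparent_fraction(
                p.f, p.T2p, p.T2t, f_apparent_TE
            )
    if n_failed:
        logger.info("voxelwise fit: %d of %d voxels failed or did not "
                    "converge", n_failed, len(idx))
    return ParameterMaps(
        maps=maps,
        mask=mask,
        model=model,
        n_failed=n_failed,
        n_fitted=len(idx),
        config=config,
    )


# --- ROI CSV I/O -----------------------------------------------------------


def read_roi_csv(path) -> SignalSeries:
    """Read an ROI-mean series CSV with columns b, TE_ms, signal."""
    df = pd.read_csv(path)
    for col in ("b", "TE_ms", "signal"):
        if col not in df.columns:
            raise FitError(f"ROI CSV {path} missing column '{col}'")
    from .acquisition import SchemeEntry

    nav = df["n_averages"] if "n_averages" in df.columns else [1] * len(df)
    scheme = AcquisitionScheme(
        [
            SchemeEntry(b=float(b), TE=float(t), n_averages=int(n))
            for b, t, n in zip(df["b"], df["TE_ms"], nav)
        ]
    )
    return SignalSeries(scheme, df["signal"].to_numpy(dtype=float))


def write_roi_csv(series: SignalSeries, path) -> None:
    pd.DataFrame(
        {
            "b": series.scheme.b,
            "TE_ms": series.scheme.TE,
            "n_averages": series.scheme.n_averages,
            "signal": series.signal,
        }
    ).to_csv(path, index=False)
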