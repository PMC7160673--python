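"""Fluorescence-polarization titrations and Hill-slope Kd fitting.

A FAM-labeled peptide (held at 10 nM) is titrated with reader protein; the
measured polarization P (reported in mP) rises as the bound fraction grows.
Readings are first scaled so the lowest-protein point sits at a requested 20
mP, converted to anisotropy A = 2P / (3 - P), and fit with a specific-binding
model with Hill slope:

    A(x) = baseline + (amax - baseline) * x**h / (kd**h + x**h)

where x is the total protein concentration in uM (ligand depletion is
negligible at 10 nM ligand against Kd >= 0.1 uM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "FitResult",
    "polarization_to_anisotropy",
    "anisotropy_to_polarization",
    "mp_to_anisotropy",
    "scale_series",
    "hill_model",
    "fit_specific_binding_hill",
    "fit_series",
    "fold_change",
]


@dataclass(frozen=True)
class TitrationSeries:
    """One FP titration: protein concentrations (uM) vs polarization (mP)."""

    peptide_id: str
    concentrations_um: tuple[float, ...]
    mp: tuple[float, ...]
    ligand_nm: float = 10.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_um, dtype=float)
        mp = np.asarray(self.mp, dtype=float)
        if conc.size != mp.size:
            raise ValueError("concentrations and polarization differ in length")
        if conc.size == 0:
            raise ValueError("titration series is empty")
        if np.any(conc <= 0):
            raise ValueError("protein concentrations must be > 0")
        d = np.diff(conc)
        if conc.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("concentrations must be strictly monotonic")
        object.__setattr__(self, "concentrations_um", tuple(float(x) for x in conc))
        object.__setattr__(self, "mp", tuple(float(x) for x in mp))


def polarization_to_anisotropy(p):
    """A = 2P / (3 - P), for polarization in fraction units (mP / 1000)."""
    p = np.asarray(p, dtype=float)
    if np.any(p >= 3):
        raise ValueError("polarization >= 3 is outside the physical domain")
    out = 2.0 * p / (3.0 - p)
    return float(out) if out.ndim == 0 else out


def anisotropy_to_polarization(a):
    """Inverse conversion, P = 3A / (2 + A)."""
    a = np.asarray(a, dtype=float)
    out = 3.0 * a / (2.0 + a)
    return float(out) if out.ndim == 0 else out


def mp_to_anisotropy(mp):
    """Convert mP readings to anisotropy (divide by 1000, then convert)."""
    return polarization_to_anisotropy(np.asarray(mp, dtype=float) / 1000.0)


def scale_series(series: TitrationSeries, requested_mp: float = 20.0) -> TitrationSeries:
    """Rescale a titration so the lowest-protein point reads ``requested_mp``.

    All mP values are multiplied by requested_mp / (mP at the lowest protein
    concentration); the operation is idempotent at the same request.
    """
    conc = np.asarray(series.concentrations_um)
    mp = np.asarray(series.mp)
    anchor = float(mp[int(np.argmin(conc))])
    if anchor <= 0:
        raise ValueError(
            "cannot scale: polarization at the lowest protein concentration is <= 0"
        )
    return replace(series, mp=tuple(mp * (requested_mp / anchor)))


def hill_model(x, kd, hill, amax, baseline):
    """Specific binding with Hill slope on anisotropy scale."""
    x = np.asarray(x, dtype=float)
    xh = np.power(x, hill)
    return baseline + (amax - baseline) * xh / (np.power(kd, hill) + xh)


@dataclass(frozen=True)
class FitResult:
    """Hill-fit estimates with standard errors and reliability flags.

    ``converged`` means the optimizer produced a finite solution on
    non-degenerate data; ``reliable`` additionally requires the fitted Kd to
    sit within 0.01x-100x of the measured concentration range (outside it the
    curve is unconstrained -- the too-weak-to-determine case).
    """

    kd: float
    hill: float
    amax: float
    baseline: float
    kd_se: float
    hill_se: float
    amax_se: float
    baseline_se: float
    converged: bool
    reliable: bool
    rmsd: float

    @classmethod
    def failed(cls) -> "FitResult":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, nan, False, False, nan)


def fit_specific_binding_hill(
    concentrations_um: Sequence[float],
    anisotropy: Sequence[float],
    fix_baseline: bool = False,
    ligand_nm: float = 10.0,
    n_restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the Hill binding model to an anisotropy curve.

    Initial values: Kd at the geometric mid-concentration, Hill slope 1,
    amplitude and baseline from the data extrema.  On failure the fit is
    retried from seeded perturbed starts.  With ``fix_baseline`` the floor is
    pinned to zero instead of fitted.
    """
    x = np.asarray(concentrations_um, dtype=float)
    a = np.asarray(anisotropy, dtype=float)
    if x.size != a.size:
        raise ValueError("concentration and anisotropy arrays differ in length")
    if x.size < 6:
        raise ValueError("at least 6 titration points are required for fitting")
    if np.ptp(a) < 1e-12:  # flat curve: nothing to fit
        return FitResult.failed()

    kd0 = float(np.exp(np.mean(np.log(x))))
    amax0, base0 = float(a.max()), float(a.min())
    span = amax0 - base0

    if fix_baseline:
        model = lambda x, kd, hill, amax: hill_model(x, kd, hill, amax, 0.0)
        p0 = [kd0, 1.0, amax0]
        lo = [1e-12, 1e-3, -1.0]
        hi = [np.inf, 50.0, 1.0]
    else:
        model = hill_model
        p0 = [kd0, 1.0, amax0, base0]
        lo = [1e-12, 1e-3, -1.0, -1.0]
        hi = [np.inf, 50.0, 1.0, 1.0]

    rng = np.random.default_rng(seed)
    popt = pcov = None
    start = list(p0)
    for attempt in range(1 + n_restarts):
        try:
            popt, pcov = curve_fit(
                model, x, a, p0=start, bounds=(lo, hi), maxfev=20000
            )
            break
        except (RuntimeError, ValueError):
            # perturb Kd and Hill multiplicatively, amplitudes additively
            start = list(p0)
            start[0] = p0[0] * float(np.exp(rng.normal(0, 1.5)))
            start[1] = float(np.clip(p0[1] * np.exp(rng.normal(0, 0.5)), lo[1], hi[1]))
            start[2] = p0[2] + float(rng.normal(0, 0.2 * span + 1e-6))
    if popt is None:
        return FitResult.failed()

    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    if fix_baseline:
        kd, hill, amax = (float(v) for v in popt)
        baseline, base_se = 0.0, 0.0
        kd_se, hill_se, amax_se = (float(v) for v in se)
    else:
        kd, hill, amax, baseline = (float(v) for v in popt)
        kd_se, hill_se, amax_se, base_se = (float(v) for v in se)

    resid = a - model(x, *popt)
    rmsd = float(np.sqrt(np.mean(resid**2)))
    reliable = bool(0.01 * x.min() <= kd <= 100.0 * x.max())
    if kd < 10.0 * ligand_nm / 1000.0:
        warnings.warn(
            f"fitted Kd ({kd:.3g} uM) is within 10x of the ligand concentration "
            f"({ligand_nm} nM); ligand depletion may bias the estimate"
        )
    return FitResult(
        kd, hill, amax, baseline,
        kd_se, hill_se, amax_se, base_se,
        converged=True, reliable=reliable, rmsd=rmsd,
    )


def fit_series(
    series: TitrationSeries,
    scale_to_mp: float | None = None,
    fix_baseline: bool = False,
    seed: int = 0,
) -> FitResult:
    """Convenience wrapper: optional 20-mP scaling, mP-to-anisotropy
    conversion, then the Hill fit."""
    s = scale_series(series, scale_to_mp) if scale_to_mp is not None else series
    return fit_specific_binding_hill(
        s.concentrations_um,
        mp_to_anisotropy(s.mp),
        fix_baseline=fix_baseline,
        ligand_nm=s.ligand_nm,
        seed=seed,
    )


def fold_change(kd_a: float, kd_b: float) -> float:
    """kd_b / kd_a: how many fold tighter binder *a* is than binder *b*."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be > 0")
    return float(kd_b) / float(kd_a)
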