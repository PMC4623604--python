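"""Global 1:1 fast-exchange K_d fitting from NMR titration ladders.

In the fast-exchange regime the observed position of a resonance is the
population-weighted average of its free and bound positions, so the shift
relative to the zero-ligand point is

    Delta_obs(L) = Delta_max * f_bound(P_tot, L_tot, Kd)

with f_bound given by the 1:1 ligand-depletion mass balance (quadratic in the
complex concentration).  All resonances that pass the significance screen are
fitted globally: one shared Kd, one Delta_max per resonance, weighted by the
per-point peak-position uncertainty (line width / SNR).  The Kd uncertainty is
estimated by Monte-Carlo resampling with a 10 % multiplicative error on the
ligand concentration and additive position noise.

Concentrations are in µM throughout; shifts in Hz relative to the first
(zero-ligand) titration point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "TitrationSeries",
    "TitrationFitResult",
    "MonteCarloResult",
    "fraction_bound",
    "peak_position_error",
    "select_fit_residues",
    "fit_global_kd",
    "monte_carlo_kd_error",
    "PAPER_MOLAR_RATIOS",
]

#: The 16-point ligand:protein molar-ratio ladder used for Kd titrations.
PAPER_MOLAR_RATIOS: tuple[float, ...] = (
    0.0, 0.1, 1.5, 3.0, 4.5, 6.0, 7.5, 9.0,
    10.5, 12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0,
)

# Kd initialisation grid: 50 log-spaced points spanning 1e-2 .. 1e3 x P_tot.
_GRID_LO_FACTOR = 1e-2
_GRID_HI_FACTOR = 1e3
_GRID_POINTS = 50


def fraction_bound(p_tot, l_tot, kd):
    """Fraction of protein bound, [PL]/P_tot, from the 1:1 depletion model.

    [PL] = ((P + L + K) - sqrt((P + L + K)^2 - 4 P L)) / 2.

    Any consistent concentration unit may be used.  ``l_tot`` may be an array.

    Parameters
    ----------
    p_tot : float
        Total protein (receptor) concentration, >= 0.
    l_tot : float or array_like
        Total ligand concentration(s), >= 0.
    kd : float
        Dissociation constant, > 0.
    """
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    p = float(p_tot)
    l = np.asarray(l_tot, dtype=float)
    if p < 0 or np.any(l < 0):
        raise ValueError("concentrations must be non-negative")
    if p == 0:
        return np.zeros_like(l) if l.ndim else 0.0
    s = p + l + kd
    # sqrt argument is >= (p - l)^2 + ... >= 0 analytically; clip for rounding
    disc = np.clip(s * s - 4.0 * p * l, 0.0, None)
    pl = 0.5 * (s - np.sqrt(disc))
    fb = np.clip(pl / p, 0.0, 1.0)
    return fb if fb.ndim else float(fb)


def peak_position_error(linewidth_hz: float, snr: float) -> float:
    """Peak-position uncertainty: line width divided by signal-to-noise."""
    if linewidth_hz <= 0:
        raise ValueError(f"linewidth must be > 0, got {linewidth_hz}")
    if snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    return linewidth_hz / snr


@dataclass
class TitrationSeries:
    """Per-resonance observed shifts across a ligand-concentration ladder.

    Attributes
    ----------
    protein_total:
        Total protein concentration in µM, constant across the ladder.
    ligand_totals:
        Total ligand concentration per titration point (µM), ascending,
        starting at 0.
    shifts:
        DataFrame, rows = resonance labels (e.g. ``"88_H"``), columns =
        titration-point index; observed shift in Hz relative to the first
        point.
    errors:
        Same shape; per-point position uncertainty in Hz (line width / SNR).
    """

    protein_total: float
    ligand_totals: np.ndarray
    shifts: pd.DataFrame
    errors: pd.DataFrame

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        if self.protein_total <= 0:
            raise ValueError("protein_total must be > 0")
        if self.ligand_totals.ndim != 1 or self.ligand_totals.size < 2:
            raise ValueError("need at least 2 titration points")
        if self.ligand_totals[0] != 0:
            raise ValueError("first titration point must have L_tot = 0")
        if np.any(np.diff(self.ligand_totals) < 0):
            raise ValueError("ligand_totals must be non-decreasing")
        if self.shifts.shape != self.errors.shape:
            raise ValueError("shifts and errors must have identical shape")
        if self.shifts.shape[1] != self.ligand_totals.size:
            raise ValueError("one shift column per titration point required")

    @property
    def n_points(self) -> int:
        return int(self.ligand_totals.size)

    @property
    def resonances(self) -> list[str]:
        return [str(r) for r in self.shifts.index]


@dataclass
class TitrationFitResult:
    """Result of a global Kd fit."""

    kd: float                      # µM
    kd_sd: float | None            # µM, filled in by monte_carlo_kd_error
    delta_max: pd.Series           # Hz per resonance
    delta_max_sd: pd.Series        # Hz, linear-LSQ asymptotic
    residuals: pd.DataFrame        # obs - model, Hz
    residues: list[str]
    chi2: float
    converged: bool
    n_eval: int
    warnings: list[str] = field(default_factory=list)

    def to_report(self) -> str:
        """Structured-text (JSON) fit report."""
        return json.dumps(
            {
                "kd_uM": self.kd,
                "kd_sd_uM": self.kd_sd,
                "delta_max_hz": self.delta_max.to_dict(),
                "delta_max_sd_hz": self.delta_max_sd.to_dict(),
                "chi2": self.chi2,
                "converged": self.converged,
                "residues": self.residues,
                "warnings": self.warnings,
            },
            indent=2,
        )


@dataclass
class MonteCarloResult:
    kd_sd: float
    kd_samples: np.ndarray
    n_failed: int


def select_fit_residues(series: TitrationSeries, csp_profile) -> list[str]:
    """Resonances significant at the titration endpoint, with full ladders.

    ``csp_profile`` is a flagged :class:`idpfrag.csp.CSPProfile` computed from
    the first versus last titration point.  A flagged residue contributes its
    per-dimension rows (``"<res>_H"``, ``"<res>_N"``) where those rows exist
    in the series with no missing values.
    """
    selected: list[str] = []
    for res, dim in csp_profile.flagged():
        label = f"{res}_{dim}"
        if label in series.shifts.index and not series.shifts.loc[label].isna().any():
            selected.append(label)
        elif str(res) in series.shifts.index and dim == "H":
            # series keyed by bare residue = single (1H) dimension
            selected.append(str(res))
    if not selected:
        raise ValueError("no fittable residues: nothing passed the significance screen")
    if len(selected) == 1:
        warnings.warn("single-residue global fit: Kd poorly constrained", stacklevel=2)
    return selected


def _weights(err: np.ndarray) -> np.ndarray:
    """Inverse-variance weights; unweighted if all uncertainties are zero."""
    if np.all(err == 0):
        return np.ones_like(err)
    safe = np.where(err > 0, err, np.nanmin(err[err > 0]))
    return 1.0 / safe**2


def _profiled_chi2(kd: float, p_tot: float, l_tot: np.ndarray,
                   y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Chi-square at fixed Kd with per-resonance Delta_max profiled out.

    For fixed Kd the model is linear in each Delta_max, so the weighted
    least-squares optimum has the closed form
    ``dmax = sum(w f y) / sum(w f^2)`` per resonance (variable projection).
    """
    fb = fraction_bound(p_tot, l_tot, kd)           # (n_points,)
    denom = (w * fb**2).sum(axis=1)                 # (n_res,)
    num = (w * fb * y).sum(axis=1)
    dmax = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    resid = y - dmax[:, None] * fb[None, :]
    return float((w * resid**2).sum()), dmax


def _fit_kd_arrays(p_tot: float, l_tot: np.ndarray, y: np.ndarray,
                   w: np.ndarray) -> tuple[float, float, np.ndarray, int, list[str]]:
    """Grid-initialised bounded refinement of Kd on raw arrays."""
    fit_warnings: list[str] = []
    grid = np.logspace(np.log10(_GRID_LO_FACTOR * p_tot),
                       np.log10(_GRID_HI_FACTOR * p_tot), _GRID_POINTS)
    chi2_grid = np.array([_profiled_chi2(k, p_tot, l_tot, y, w)[0] for k in grid])
    i_best = int(np.argmin(chi2_grid))
    if i_best in (0, _GRID_POINTS - 1):
        fit_warnings.append(
            f"Kd initialisation hit the grid boundary ({grid[i_best]:.3g} µM); "
            "the ladder may not constrain Kd"
        )
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, _GRID_POINTS - 1)]

    res = minimize_scalar(
        lambda lk: _profiled_chi2(10.0**lk, p_tot, l_tot, y, w)[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"Kd fit failed to converge: {res.message}")
    kd = float(10.0**res.x)
    chi2, dmax = _profiled_chi2(kd, p_tot, l_tot, y, w)
    return kd, chi2, dmax, int(res.nfev) + _GRID_POINTS, fit_warnings


def fit_global_kd(series: TitrationSeries, residues: Sequence[str]) -> TitrationFitResult:
    """Fit one global Kd and per-resonance Delta_max to selected resonances.

    Minimises sum_{r,p} ((obs - Delta_max_r * f_bound_p) / sigma_pos)^2.
    Kd is initialised by a 50-point log-spaced grid search spanning
    1e-2 .. 1e3 x P_tot, then refined by bounded scalar minimisation in
    log10(Kd) with Delta_max profiled out in closed form at every step.
    """
    residues = [str(r) for r in residues]
    if not residues:
        raise ValueError("no residues selected for fitting")
    missing = [r for r in residues if r not in series.shifts.index]
    if missing:
        raise KeyError(f"resonances absent from series: {missing}")
    if series.n_points < 4:
        raise ValueError("need >= 4 titration points for a Kd fit")

    y = series.shifts.loc[residues].to_numpy(dtype=float)
    err = series.errors.loc[residues].to_numpy(dtype=float)
    if not np.any(np.abs(y) > 0):
        raise ValueError("no signal: all observed shifts are zero")
    w = _weights(err)

    p_tot = series.protein_total
    l_tot = series.ligand_totals
    kd, chi2, dmax, n_eval, fit_warnings = _fit_kd_arrays(p_tot, l_tot, y, w)
    for msg in fit_warnings:
        warnings.warn(msg, stacklevel=2)

    fb = fraction_bound(p_tot, l_tot, kd)
    denom = (w * fb**2).sum(axis=1)
    dmax_sd = np.sqrt(np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), np.inf))
    resid = y - dmax[:, None] * fb[None, :]

    return TitrationFitResult(
        kd=kd,
        kd_sd=None,
        delta_max=pd.Series(dmax, index=residues, name="delta_max_hz"),
        delta_max_sd=pd.Series(dmax_sd, index=residues, name="delta_max_sd_hz"),
        residuals=pd.DataFrame(resid, index=residues, columns=series.shifts.columns),
        residues=residues,
        chi2=chi2,
        converged=True,
        n_eval=n_eval,
        warnings=fit_warnings,
    )


def monte_carlo_kd_error(
    series: TitrationSeries,
    residues: Sequence[str],
    n_iter: int = 500,
    seed: int | None = None,
    conc_error: float = 0.10,
    position_noise: bool = True,
    shared_conc_scale: bool = False,
) -> MonteCarloResult:
    """Monte-Carlo Kd uncertainty from concentration and position errors.

    Each replicate multiplies every ligand total by ``Normal(1, conc_error)``
    (independently per point by default; a single shared scale factor with
    ``shared_conc_scale=True``), adds ``Normal(0, sigma_pos)`` to every
    observed shift when ``position_noise`` is on, and refits.  The reported
    uncertainty is the sample SD of the replicate Kd values.

    Raises if more than 20 % of replicates fail to converge.
    """
    if seed is None:
        raise ValueError("seed is mandatory for Monte-Carlo error estimation")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 to form a standard deviation")
    # validate the base fit before resampling
    fit_global_kd(series, residues)

    residues = [str(r) for r in residues]
    y0 = series.shifts.loc[residues].to_numpy(dtype=float)
    sigma = series.errors.loc[residues].to_numpy(dtype=float)
    w = _weights(sigma)
    p_tot = series.protein_total

    rng = np.random.default_rng(seed)
    kds: list[float] = []
    n_failed = 0
    for _ in range(n_iter):
        if conc_error > 0:
            if shared_conc_scale:
                l_rep = series.ligand_totals * rng.normal(1.0, conc_error)
            else:
                l_rep = series.ligand_totals * rng.normal(1.0, conc_error,
                                                          size=series.n_points)
            l_rep = np.clip(l_rep, 0.0, None)
        else:
            l_rep = series.ligand_totals.copy()
        y = y0
        if position_noise:
            y = y0 + rng.normal(0.0, 1.0, size=y0.shape) * sigma
        try:
            kd_rep, _, _, _, rep_warn = _fit_kd_arrays(p_tot, l_rep, y, w)
            if rep_warn:  # boundary Kd counts as non-convergent
                n_failed += 1
            else:
                kds.append(kd_rep)
        except (ValueError, RuntimeError):
            n_failed += 1
    if n_failed > 0.2 * n_iter or len(kds) < 2:
        raise RuntimeError(
            f"Monte-Carlo unstable: {n_failed}/{n_iter} replicates failed to converge"
        )
    samples = np.asarray(kds)
    return MonteCarloResult(
        kd_sd=float(np.std(samples, ddof=1)),
        kd_samples=samples,
        n_failed=n_failed,
    )
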