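"""Displacement and functional-assay analysis.

Four readouts quantify whether a compound displaces the disordered domain
(p27-D2) from its kinase target (Cdk2/cyclin A):

* **Ratiometric NMR populations** — when free and bound resonances coexist
  in slow exchange, the free-state population of a residue is
  p_f = I_free / (I_free + I_bound).  Comparing conditions with and without
  compound gives the ratios R_f = p_f(with)/p_f(without) and
  R_b = p_b(with)/p_b(without); displacement shows as R_f > 1 and R_b < 1
  beyond the propagated replicate error.
* **Fluorescence anisotropy** — direct binding of a labelled probe is fitted
  as r = r_free + (r_bound - r_free) * f_bound with f_bound from the 1:1
  ligand-depletion quadratic; competitive displacement is summarised by a
  four-parameter logistic (4PL) IC50.
* **Ternary competition model** — mass-action equilibria C+D<->CD and
  D+L<->DL (optionally C+L<->CL), solved by damped fixed-point iteration on
  the free concentrations, predict species distributions and displacement
  IC50s from dissociation constants.
* **Kinase activity** — relative change of percent activity versus baseline
  classifies activation (positive) against inhibition (negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.stats import spearmanr

from .titration import fraction_bound

__all__ = [
    "PeakDoublet",
    "DisplacementProfile",
    "AnisotropySeries",
    "DirectBindingFit",
    "DoseResponseFit",
    "TernarySolution",
    "free_population",
    "build_displacement_profile",
    "displacement_call",
    "fit_direct_binding",
    "fit_ic50",
    "average_replicates",
    "solve_ternary",
    "predict_displacement_ic50",
    "activity_analysis",
]


@dataclass
class PeakDoublet:
    """Free/bound intensity pair for one residue in one replicate."""

    residue: str
    i_free: float
    i_bound: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.i_free < 0 or self.i_bound < 0:
            raise ValueError("intensities must be >= 0")
        if self.i_free + self.i_bound == 0:
            raise ValueError(f"residue {self.residue}: both intensities are zero")


def free_population(doublet: PeakDoublet) -> tuple[float, float]:
    """(p_f, p_b): free and bound populations as fractions of the total."""
    total = doublet.i_free + doublet.i_bound
    p_f = doublet.i_free / total
    return p_f, 1.0 - p_f


@dataclass
class DisplacementProfile:
    """Per-residue population ratios with and without compound.

    ``data`` columns: ``pf_without``, ``pf_without_sd``, ``pf_with``,
    ``pf_with_sd``, ``pb_*`` analogues, ``R_f``, ``R_f_sd``, ``R_b``,
    ``R_b_sd``; index = residue.
    """

    data: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def build_displacement_profile(doublets: pd.DataFrame) -> DisplacementProfile:
    """Assemble a displacement profile from a doublet table.

    ``doublets`` columns: ``residue``, ``I_free``, ``I_bound``,
    ``replicate``, ``condition`` (``"without"``/``"with"``).  Populations are
    averaged over replicates (sample SD); the ratio SDs follow from
    first-order error propagation.  Residues missing a condition are skipped
    and listed in ``skipped``.
    """
    required = {"residue", "I_free", "I_bound", "replicate", "condition"}
    if not required <= set(doublets.columns):
        raise ValueError(f"doublet table needs columns {sorted(required)}")
    rows = {}
    skipped: list[str] = []
    for residue, grp in doublets.groupby("residue", sort=True):
        conds = set(grp["condition"])
        if not {"without", "with"} <= conds:
            skipped.append(str(residue))
            continue
        stats = {}
        for cond in ("without", "with"):
            sub = grp[grp["condition"] == cond]
            pf = np.array([
                free_population(PeakDoublet(str(residue), f, b, int(r)))[0]
                for f, b, r in zip(sub["I_free"], sub["I_bound"], sub["replicate"])
            ])
            stats[cond] = (pf.mean(), pf.std(ddof=1) if pf.size > 1 else 0.0)
        (m_wo, s_wo), (m_w, s_w) = stats["without"], stats["with"]
        if m_wo in (0.0, 1.0) or m_w in (0.0, 1.0):
            # a zero population makes one of the ratios undefined
            skipped.append(str(residue))
            continue
        r_f = m_w / m_wo
        r_f_sd = r_f * np.hypot(s_w / m_w, s_wo / m_wo)
        r_b = (1 - m_w) / (1 - m_wo)
        r_b_sd = r_b * np.hypot(s_w / (1 - m_w), s_wo / (1 - m_wo))
        rows[str(residue)] = {
            "pf_without": m_wo, "pf_without_sd": s_wo,
            "pf_with": m_w, "pf_with_sd": s_w,
            "pb_without": 1 - m_wo, "pb_without_sd": s_wo,
            "pb_with": 1 - m_w, "pb_with_sd": s_w,
            "R_f": r_f, "R_f_sd": r_f_sd, "R_b": r_b, "R_b_sd": r_b_sd,
        }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "residue"
    return DisplacementProfile(data=data, skipped=skipped)


def displacement_call(profile: DisplacementProfile, n_sd: float = 1.0) -> pd.Series:
    """Per-residue verdict: ``displaced`` / ``not_displaced`` / ``indeterminate``.

    Displaced requires R_f > 1 and R_b < 1 with each inequality exceeding
    ``n_sd`` propagated standard deviations.  The right direction within
    error is indeterminate; the wrong direction (or exact identity) is not
    displaced.
    """
    verdicts = {}
    for residue, row in profile.data.iterrows():
        direction = row["R_f"] > 1.0 and row["R_b"] < 1.0
        if not direction:
            verdicts[residue] = "not_displaced"
        elif (row["R_f"] - n_sd * row["R_f_sd"] > 1.0
              and row["R_b"] + n_sd * row["R_b_sd"] < 1.0):
            verdicts[residue] = "displaced"
        else:
            verdicts[residue] = "indeterminate"
    return pd.Series(verdicts, name="verdict")


@dataclass
class AnisotropySeries:
    """Anisotropy readings along a titrant ladder at fixed probe."""

    concentrations: np.ndarray   # titrant totals (any unit, e.g. nM)
    anisotropy: np.ndarray
    sd: np.ndarray | None = None
    probe_total: float = 20.0    # nM

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.probe_total <= 0:
            raise ValueError("probe_total must be > 0")


@dataclass
class DirectBindingFit:
    kd: float
    kd_sd: float
    r_free: float
    r_bound: float
    residuals: np.ndarray
    saturated: bool


def anisotropy_model(l_tot, kd, r_free, r_bound, probe_total):
    """r(L) = r_free + (r_bound - r_free) * f_bound, with probe depletion."""
    fb = fraction_bound(probe_total, l_tot, kd)
    return r_free + (r_bound - r_free) * fb


def fit_direct_binding(series: AnisotropySeries) -> DirectBindingFit:
    """Weighted 1:1 depletion fit of a direct-binding anisotropy ladder."""
    if series.concentrations.size < 5:
        raise ValueError("need >= 5 titration points")
    x, y = series.concentrations, series.anisotropy
    sigma = series.sd if series.sd is not None and np.all(series.sd > 0) else None
    p0 = (max(np.median(x[x > 0]), series.probe_total), float(y[0]), float(y[-1]))
    popt, pcov = curve_fit(
        lambda l, kd, rf, rb: anisotropy_model(l, kd, rf, rb, series.probe_total),
        x, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
        bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    kd, r_free, r_bound = popt
    kd_sd = float(np.sqrt(pcov[0, 0]))
    fb_max = fraction_bound(series.probe_total, x[-1], kd)
    saturated = bool(fb_max >= 0.9)
    if not saturated:
        warnings.warn(
            f"ladder does not reach saturation (max f_bound = {fb_max:.2f}); "
            "Kd uncertainty is wide", stacklevel=2,
        )
    resid = y - anisotropy_model(x, kd, r_free, r_bound, series.probe_total)
    return DirectBindingFit(float(kd), kd_sd, float(r_free), float(r_bound),
                            resid, saturated)


@dataclass
class DoseResponseFit:
    ic50: float
    ic50_sd: float
    hill: float
    hill_sd: float
    top: float
    bottom: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.top == self.bottom:
            raise ValueError("top and bottom must differ")

    def response_at(self, x):
        return _four_pl(np.asarray(x, dtype=float), np.log10(self.ic50),
                        self.hill, self.top, self.bottom)


def _four_pl(x, log_ic50, h, top, bottom):
    ic50 = 10.0 ** log_ic50
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / ic50) ** h, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average replicate dose-response tables (columns ``conc, response``).

    Returns columns ``conc, response, sd`` (sample SD across replicates).
    All replicates must share the same concentration ladder.
    """
    concs = [np.asarray(t["conc"], dtype=float) for t in tables]
    for c in concs[1:]:
        if not np.allclose(c, concs[0]):
            raise ValueError("replicates must share the same concentration ladder")
    resp = np.vstack([np.asarray(t["response"], dtype=float) for t in tables])
    return pd.DataFrame({
        "conc": concs[0],
        "response": resp.mean(axis=0),
        "sd": resp.std(axis=0, ddof=1) if resp.shape[0] > 1 else np.zeros(resp.shape[1]),
    })


def fit_ic50(concentrations, responses, sd=None) -> DoseResponseFit:
    """Four-parameter logistic fit: bottom + (top-bottom)/(1 + (x/IC50)^h).

    IC50 is fitted in log space; the hill slope floats.  A non-monotone
    mean trend (|Spearman rho| < 0.8) triggers a warning but not an error.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 concentrations for a 4PL fit")
    rho = spearmanr(x, y).statistic
    if not np.isfinite(rho) or abs(rho) < 0.8:
        warnings.warn(f"dose-response trend is not monotone (Spearman rho = {rho:.2f})",
                      stacklevel=2)
    decreasing = y[np.argmax(x)] < y[np.argmin(x)]
    pos = x[x > 0]
    p0 = (float(np.log10(np.sqrt(pos.min() * pos.max()))),
          1.0 if decreasing else -1.0,
          float(y.max() if decreasing else y.min()),
          float(y.min() if decreasing else y.max()))
    sigma = np.asarray(sd, dtype=float) if sd is not None else None
    if sigma is not None and np.any(sigma <= 0):
        sigma = None
    popt, pcov = curve_fit(_four_pl, x, y, p0=p0, sigma=sigma,
                           absolute_sigma=sigma is not None, maxfev=20000)
    log_ic50, h, top, bottom = popt
    perr = np.sqrt(np.diag(pcov))
    ic50 = float(10.0 ** log_ic50)
    ic50_sd = float(ic50 * np.log(10) * perr[0])  # delta method
    return DoseResponseFit(ic50, ic50_sd, float(h), float(perr[1]),
                           float(top), float(bottom),
                           y - _four_pl(x, *popt))


@dataclass
class TernarySolution:
    """Species concentrations of the C/D/L competition equilibrium."""

    c_free: float
    d_free: float
    l_free: float
    cd: float
    dl: float
    cl: float
    residual: float
    iterations: int

    def as_dict(self) -> dict[str, float]:
        return {"C_free": self.c_free, "D_free": self.d_free,
                "L_free": self.l_free, "CD": self.cd, "DL": self.dl,
                "CL": self.cl}


def solve_ternary(c_tot: float, d_tot: float, l_tot: float,
                  kd_cd: float, kd_dl: float,
                  kd_cl: float | None = None,
                  tol_factor: float = 1e-10, max_iter: int = 200000) -> TernarySolution:
    """Solve the competition equilibria C+D<->CD, D+L<->DL (opt. C+L<->CL).

    Damped fixed-point iteration on the free concentrations: each total
    constrains its free species via
    ``C_free = C_tot / (1 + D_free/Kd_CD + L_free/Kd_CL)`` etc.; geometric
    damping makes the map a contraction.  Converges when every mass-balance
    residual is below ``tol_factor * max(totals)``.
    """
    if min(c_tot, d_tot, l_tot) < 0:
        raise ValueError("totals must be >= 0")
    if kd_cd <= 0 or kd_dl <= 0 or (kd_cl is not None and kd_cl <= 0):
        raise ValueError("dissociation constants must be > 0")
    inv_cl = 1.0 / kd_cl if kd_cl is not None else 0.0
    scale = max(c_tot, d_tot, l_tot, 1e-300)
    tol = tol_factor * scale

    c, d, l = c_tot, d_tot, l_tot
    damp = 0.5
    for it in range(1, max_iter + 1):
        c_new = c_tot / (1.0 + d / kd_cd + l * inv_cl) if c_tot > 0 else 0.0
        d_new = d_tot / (1.0 + c / kd_cd + l / kd_dl) if d_tot > 0 else 0.0
        l_new = l_tot / (1.0 + d / kd_dl + c * inv_cl) if l_tot > 0 else 0.0
        # geometric damping keeps iterates positive and contracts the map
        c = c ** (1 - damp) * c_new ** damp if c_tot > 0 else 0.0
        d = d ** (1 - damp) * d_new ** damp if d_tot > 0 else 0.0
        l = l ** (1 - damp) * l_new ** damp if l_tot > 0 else 0.0
        cd = c * d / kd_cd
        dl = d * l / kd_dl
        cl = c * l * inv_cl
        res = max(abs(c + cd + cl - c_tot),
                  abs(d + cd + dl - d_tot),
                  abs(l + dl + cl - l_tot))
        if res < tol:
            return TernarySolution(c, d, l, cd, dl, cl, res, it)
    raise RuntimeError(
        f"ternary solver did not converge in {max_iter} iterations "
        f"(residual {res:.3g}, tolerance {tol:.3g})"
    )


def predict_displacement_ic50(c_tot: float, d_tot: float,
                              kd_cd: float, kd_dl: float,
                              kd_cl: float | None = None) -> float:
    """Competitor total at which the CD complex is reduced to half its
    no-competitor value — the model-predicted displacement IC50."""
    cd0 = solve_ternary(c_tot, d_tot, 0.0, kd_cd, kd_dl, kd_cl).cd
    if cd0 <= 0:
        raise ValueError("no CD complex forms without competitor")

    def f(log_l: float) -> float:
        return solve_ternary(c_tot, d_tot, 10.0 ** log_l, kd_cd, kd_dl, kd_cl).cd - 0.5 * cd0

    lo, hi = -6.0, 3.0
    while f(hi) > 0 and hi < 15:
        hi += 3.0
    return float(10.0 ** brentq(f, lo, hi, xtol=1e-12))


def activity_analysis(activities: Mapping[str, float],
                      baseline_key: str = "baseline") -> pd.DataFrame:
    """Relative activity changes versus baseline, classified by sign.

    ``activities`` maps condition name -> percent activity; the baseline
    condition must be present and non-zero.  Returns a DataFrame indexed by
    condition with ``activity_pct``, ``relative_change_pct`` (100 *
    (treated - baseline) / baseline) and ``classification``
    (``activation``/``inhibition``/``unchanged``).
    """
    if baseline_key not in activities:
        raise ValueError(f"baseline condition {baseline_key!r} missing")
    baseline = float(activities[baseline_key])
    if baseline == 0:
        raise ValueError("baseline activity is zero; relative change undefined")
    rows = {}
    for cond, value in activities.items():
        if cond == baseline_key:
            continue
        change = 100.0 * (float(value) - baseline) / baseline
        rows[cond] = {
            "activity_pct": float(value),
            "relative_change_pct": change,
            "classification": ("activation" if change > 0
                               else "inhibition" if change < 0 else "unchanged"),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "condition"
    return out
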