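"""Chemical-shift-perturbation (CSP) analysis of 2D 1H-15N titration data.

A CSP is the change in a backbone-amide resonance position on ligand
addition, Delta_delta = |delta_perturbed - delta_reference|, evaluated per
dimension (1H and 15N) rather than as a combined value: for weakly binding
fragments against a disordered target the 1H perturbations dominate and a
combined shift would dilute them.  A residue is called significant in a
dimension only if its CSP exceeds BOTH

  i)  the digital spectral resolution of that dimension (in Hz), and
  ii) the population threshold Delta_delta_ave + 2*sigma,

where the mean and sample SD are taken over all observed residues of that
spectrum pair.  Significant residues are then mapped onto the D2 sub-regions
of p27 (D2.1 around W60, D2.2 around W76, D2.3 around the F87-Y88-Y89
aromatic cluster) to classify the perturbation footprint:

* Group 1 — CSPs confined to D2.3;
* Group 2 — D2.3 plus at least one of D2.1/D2.2.

Comparisons are carried out in Hz so printed resolution floors apply
directly; ppm values are converted with the nucleus Larmor frequency
(15N/1H gyromagnetic ratio 0.10136767).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "CSPProfile",
    "SubRegionMap",
    "GAMMA_N_OVER_H",
    "read_peak_list",
    "write_peak_list",
    "compute_csp",
    "combined_csp",
    "flag_significant",
    "classify_binding_pattern",
]

logger = logging.getLogger(__name__)

#: |gamma(15N)/gamma(1H)|: 15N Larmor frequency as a fraction of the 1H one.
GAMMA_N_OVER_H = 0.10136767

_PEAK_COLUMNS = ["residue", "dH_ppm", "dN_ppm", "intensity", "lw_H_hz", "lw_N_hz", "snr"]


@dataclass
class PeakList:
    """One 2D 1H-15N peak list: one row per assigned amide resonance.

    Residues are keyed by full-length human p27 numbering as strings;
    tryptophan side-chain indole NH rows use the key ``"s-<residue>"``.
    """

    spectrum_id: str
    field_mhz: float
    data: pd.DataFrame  # columns: _PEAK_COLUMNS, residue as str

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ValueError("spectrometer 1H frequency must be > 0")
        df = self.data.copy()
        df["residue"] = df["residue"].astype(str)
        if df["residue"].duplicated().any():
            dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
            raise ValueError(f"duplicate residue keys in peak list: {dupes}")
        self.data = df.set_index("residue", drop=False) if df.index.name != "residue" else df

    @property
    def residues(self) -> list[str]:
        return list(self.data["residue"])

    @property
    def n_freq_mhz(self) -> float:
        """15N Larmor frequency implied by the 1H field."""
        return self.field_mhz * GAMMA_N_OVER_H


def read_peak_list(path: str | Path, spectrum_id: str | None = None) -> PeakList:
    """Read a TSV peak list with a ``# field_MHz=<f>`` header comment."""
    path = Path(path)
    field_mhz = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.search(r"field_MHz\s*=\s*([0-9.]+)", line)
                if m:
                    field_mhz = float(m.group(1))
            else:
                break
    if field_mhz is None:
        raise ValueError(f"{path}: missing '# field_MHz=<f>' header")
    df = pd.read_csv(path, sep="\t", comment="#", names=_PEAK_COLUMNS, header=None,
                     dtype={"residue": str})
    # tolerate a column-name header row
    if df.iloc[0]["residue"] == "residue":
        df = df.iloc[1:].reset_index(drop=True)
        for c in _PEAK_COLUMNS[1:]:
            df[c] = df[c].astype(float)
    return PeakList(spectrum_id or path.stem, field_mhz, df)


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# field_MHz={peaks.field_mhz}\n")
        fh.write("\t".join(_PEAK_COLUMNS) + "\n")
        peaks.data[_PEAK_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


@dataclass
class SubRegionMap:
    """Residue ranges (inclusive) of the p27-D2 small-molecule sub-regions.

    Defaults extend the marker residues (W60/N61, E75-W76-Q77, F87-Y88-Y89)
    symmetrically; override for other constructs.
    """

    d2_1: tuple[int, int] = (58, 70)
    d2_2: tuple[int, int] = (71, 81)
    d2_3: tuple[int, int] = (85, 90)
    markers: tuple[int, ...] = (60, 76, 88)

    def __post_init__(self) -> None:
        spans = sorted([self.d2_1, self.d2_2, self.d2_3])
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("sub-region ranges must not overlap")

    def region_of(self, residue: int) -> str | None:
        for name, (lo, hi) in (("D2.1", self.d2_1), ("D2.2", self.d2_2),
                               ("D2.3", self.d2_3)):
            if lo <= residue <= hi:
                return name
        return None


@dataclass
class CSPProfile:
    """Per-residue, per-dimension shift perturbations with significance flags.

    ``data`` rows are residues; columns ``dd_H_hz``, ``dd_N_hz``, ``dd_H_ppm``,
    ``dd_N_ppm`` and, once flagged, boolean ``sig_H``/``sig_N``.  ``stats``
    maps dimension -> ``{mean, sd, threshold, floor}`` (Hz).
    """

    data: pd.DataFrame
    field_mhz: float
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def flagged(self) -> list[tuple[str, str]]:
        """(residue, dimension) pairs flagged significant."""
        out: list[tuple[str, str]] = []
        for dim in ("H", "N"):
            col = f"sig_{dim}"
            if col in self.data.columns:
                out.extend((str(r), dim) for r in self.data.index[self.data[col]])
        return out

    def flagged_residues(self) -> set[int]:
        """Backbone residue numbers with a flag in either dimension
        (side-chain rows ``s-<n>`` map to residue ``n``)."""
        nums = set()
        for res, _dim in self.flagged():
            nums.add(int(res[2:]) if res.startswith("s-") else int(res))
        return nums


def compute_csp(reference: PeakList, perturbed: PeakList) -> CSPProfile:
    """Per-residue |Delta_delta| between two peak lists, in ppm and Hz.

    Residues present in only one list are omitted with a log message.
    Raises on a field-strength mismatch (Hz floors would not be comparable).
    """
    if not np.isclose(reference.field_mhz, perturbed.field_mhz):
        raise ValueError(
            f"field strength mismatch: {reference.field_mhz} vs {perturbed.field_mhz} MHz"
        )
    common = [r for r in reference.residues if r in set(perturbed.residues)]
    dropped = (set(reference.residues) | set(perturbed.residues)) - set(common)
    if dropped:
        logger.warning("residues present in only one peak list omitted: %s",
                       sorted(dropped))
        warnings.warn(f"{len(dropped)} residue(s) present in only one peak list omitted",
                      stacklevel=2)
    ref = reference.data.loc[common]
    per = perturbed.data.loc[common]
    dd_h_ppm = (per["dH_ppm"] - ref["dH_ppm"]).abs()
    dd_n_ppm = (per["dN_ppm"] - ref["dN_ppm"]).abs()
    data = pd.DataFrame(
        {
            "dd_H_ppm": dd_h_ppm,
            "dd_N_ppm": dd_n_ppm,
            "dd_H_hz": dd_h_ppm * reference.field_mhz,
            "dd_N_hz": dd_n_ppm * reference.n_freq_mhz,
        },
        index=pd.Index(common, name="residue"),
    )
    return CSPProfile(data=data, field_mhz=reference.field_mhz)


def combined_csp(profile: CSPProfile, n_weight: float = 0.14) -> pd.Series:
    """Optional combined 1H/15N CSP, sqrt(dH^2 + (w*dN)^2) in ppm.

    Provided for cross-comparison only; the significance criterion is
    per-dimension by default because combined values mask 1H-dominated
    perturbations.  ``n_weight`` is the conventional 15N scaling factor.
    """
    return np.sqrt(profile.data["dd_H_ppm"] ** 2
                   + (n_weight * profile.data["dd_N_ppm"]) ** 2)


def flag_significant(profile: CSPProfile, resolution_h: float,
                     resolution_n: float, use_sem: bool = False) -> CSPProfile:
    """Apply the dual significance criterion per dimension.

    A residue is flagged in a dimension iff its CSP (Hz) strictly exceeds
    both the spectral-resolution floor and Delta_delta_ave + 2*sigma, with
    the mean and sample SD computed over all observed residues in that
    dimension.  ``use_sem=True`` substitutes the standard error of the mean
    for sigma.  Requires >= 3 residues (the SD is unstable below that).
    """
    floors = {"H": float(resolution_h), "N": float(resolution_n)}
    data = profile.data.copy()
    stats: dict[str, dict[str, float]] = {}
    for dim in ("H", "N"):
        vals = data[f"dd_{dim}_hz"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            raise ValueError(
                f"need >= 3 residues with finite CSPs in the {dim} dimension, "
                f"got {vals.size}"
            )
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if use_sem:
            sd /= np.sqrt(vals.size)
        threshold = mean + 2.0 * sd
        col = data[f"dd_{dim}_hz"]
        data[f"sig_{dim}"] = (col > floors[dim]) & (col > threshold)
        stats[dim] = {"mean": mean, "sd": sd, "threshold": threshold,
                      "floor": floors[dim]}
    return CSPProfile(data=data, field_mhz=profile.field_mhz, stats=stats)


def classify_binding_pattern(profile: CSPProfile, region_map: SubRegionMap | None = None) -> str:
    """Classify a flagged CSP footprint.

    Returns ``"group1"`` (flags only in D2.3), ``"group2"`` (D2.3 plus at
    least one of D2.1/D2.2), ``"nonbinder"`` (no flags) or ``"ambiguous"``
    (anything else, e.g. flags outside sub-domain D2).
    """
    if not any(c.startswith("sig_") for c in profile.data.columns):
        raise ValueError("profile has no significance flags; run flag_significant first")
    region_map = region_map or SubRegionMap()
    residues = profile.flagged_residues()
    if not residues:
        return "nonbinder"
    regions = {region_map.region_of(r) for r in residues}
    if None in regions:
        return "ambiguous"
    if regions == {"D2.3"}:
        return "group1"
    if "D2.3" in regions:
        return "group2"
    return "ambiguous"
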