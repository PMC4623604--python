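"""Synthetic-data generators with the statistical structure each analysis
stage assumes.

Raw spectra, assay plates and MD trajectories from fragment-screening
campaigns are rarely deposited, so every downstream module here is exercised
against generated inputs whose ground truth is known exactly:

* fast-exchange titration ladders — per-residue shift trajectories
  ``delta_obs = f_bound * Delta_max + noise`` over the canonical 16-point
  molar-ratio ladder at 100 µM protein, with additive Gaussian position
  noise at the digital resolutions of the experiment (2.4 Hz 1H / 1.7 Hz
  15N at 800 MHz);
* two-state distance trajectories — a discrete-frame two-state Markov chain
  (compact/extended) emitting Gaussian pairwise distances per state, with
  the true state sequence retained for recovery tests;
* combinatorial scaffold x substituent SMILES libraries with controlled
  scaffold multiplicities and a deterministic admixture of
  invalid/inorganic/isotope decoys, plus a mock HTS frequency table.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .csp import PeakList
from .mdstates import PAIR_LABELS, DistanceStateSeries
from .titration import PAPER_MOLAR_RATIOS, TitrationSeries, fraction_bound

__all__ = [
    "ResidueSignal",
    "TitrationSimSpec",
    "TwoStateTrajectorySpec",
    "LibrarySimSpec",
    "SimulatedLibrary",
    "simulate_titration",
    "titration_peak_lists",
    "simulate_two_state_trajectory",
    "simulate_library",
    "default_titration_spec",
    "fig9_printed_spec",
    "default_two_state_spec",
    "default_library_spec",
]


# ---------------------------------------------------------------------------
# titration ladders

@dataclass
class ResidueSignal:
    """Ground-truth response of one residue: saturation shift and free position."""

    residue: int
    delta_max_h_hz: float
    delta_max_n_hz: float = 0.0
    delta_free_h_ppm: float = 8.2
    delta_free_n_ppm: float = 120.0


@dataclass
class TitrationSimSpec:
    """Conditions of a simulated 1:1 fast-exchange titration.

    Defaults are the canonical experiment: 100 µM protein, the 16-point
    ratio ladder 1:0 ... 1:30, position noise at the 2.4/1.7 Hz digital
    resolutions, and peak-position uncertainties of linewidth/SNR.
    """

    residues: Sequence[ResidueSignal]
    protein_total_uM: float = 100.0
    molar_ratios: Sequence[float] = PAPER_MOLAR_RATIOS
    kd_true_mM: float = 2.2
    noise_sd_h: float = 2.4     # Hz, additive position noise per point
    noise_sd_n: float = 1.7     # Hz
    linewidth_h: float = 24.0   # Hz
    linewidth_n: float = 17.0   # Hz
    snr: float = 10.0
    field_mhz: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        ratios = np.asarray(self.molar_ratios, dtype=float)
        if np.any(ratios < 0):
            raise ValueError("molar ratios must be non-negative")
        if np.any(np.diff(ratios) < 0):
            raise ValueError("molar ratios must be non-decreasing")
        if self.protein_total_uM <= 0:
            raise ValueError("protein_total_uM must be > 0")
        if self.kd_true_mM <= 0:
            raise ValueError("kd_true must be > 0")
        if self.noise_sd_h < 0 or self.noise_sd_n < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.residues:
            raise ValueError("at least one residue signal required")

    @property
    def kd_true_uM(self) -> float:
        return self.kd_true_mM * 1000.0

    @property
    def ligand_totals_uM(self) -> np.ndarray:
        return np.asarray(self.molar_ratios, dtype=float) * self.protein_total_uM

    def responsive_residues(self) -> list[int]:
        """Ground truth: residues with a non-zero 1H saturation shift."""
        return [r.residue for r in self.residues if r.delta_max_h_hz != 0]


def simulate_titration(spec: TitrationSimSpec) -> TitrationSeries:
    """Generate a titration series under the 1:1 depletion model.

    Each resonance row (``"<res>_H"``, ``"<res>_N"``) carries
    ``f_bound * Delta_max + Normal(0, noise_sd)`` in Hz relative to the
    zero-ligand point; position uncertainties are linewidth/SNR.
    Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    l_tot = spec.ligand_totals_uM
    fb = fraction_bound(spec.protein_total_uM, l_tot, spec.kd_true_uM)
    n_pts = l_tot.size
    rows, errs, labels = [], [], []
    for sig in spec.residues:
        for dim, dmax, noise_sd, lw in (
            ("H", sig.delta_max_h_hz, spec.noise_sd_h, spec.linewidth_h),
            ("N", sig.delta_max_n_hz, spec.noise_sd_n, spec.linewidth_n),
        ):
            noise = rng.normal(0.0, noise_sd, size=n_pts) if noise_sd > 0 else np.zeros(n_pts)
            rows.append(fb * dmax + noise)
            errs.append(np.full(n_pts, lw / spec.snr))
            labels.append(f"{sig.residue}_{dim}")
    shifts = pd.DataFrame(rows, index=labels)
    errors = pd.DataFrame(errs, index=labels)
    return TitrationSeries(spec.protein_total_uM, l_tot, shifts, errors)


def titration_peak_lists(spec: TitrationSimSpec,
                         series: TitrationSeries | None = None) -> list[PeakList]:
    """Absolute peak lists (one per titration point) consistent with a series.

    Converts the relative Hz shifts back to absolute ppm positions using
    each residue's free-state position, for feeding the CSP pipeline.
    """
    series = series if series is not None else simulate_titration(spec)
    n_freq = spec.field_mhz * 0.10136767
    lists = []
    for p in range(series.n_points):
        recs = []
        for sig in spec.residues:
            dh = sig.delta_free_h_ppm + series.shifts.loc[f"{sig.residue}_H"].iloc[p] / spec.field_mhz
            dn = sig.delta_free_n_ppm + series.shifts.loc[f"{sig.residue}_N"].iloc[p] / n_freq
            recs.append({
                "residue": str(sig.residue), "dH_ppm": dh, "dN_ppm": dn,
                "intensity": 1.0, "lw_H_hz": spec.linewidth_h,
                "lw_N_hz": spec.linewidth_n, "snr": spec.snr,
            })
        lists.append(PeakList(f"point{p}", spec.field_mhz, pd.DataFrame(recs)))
    return lists


def default_titration_spec(kd_true_mM: float = 2.2, seed: int = 0,
                           noise_sd_h: float = 2.4,
                           noise_sd_n: float = 1.7) -> TitrationSimSpec:
    """The canonical simulated experiment: a Group 2-like footprint.

    Responsive residues follow the W60/N61, E75-W76-Q77 and F87-Y88-Y89
    clusters.  Per-residue saturation shifts are not tabulated in screening
    reports; they are set in the upper half of the plausible 20-80 Hz band
    because the experiment's own reported relative Kd uncertainty (~14% at
    2.4 Hz digital resolution) requires that much aggregate signal — a
    Cramér-Rao power analysis of the 16-point design shows weaker responders
    could not have produced it.  Thirty-odd flat residues across the rest of
    the domain carry no response.
    """
    responsive = [
        ResidueSignal(60, 75.0, 9.0, 8.05, 121.5),
        ResidueSignal(61, 55.0, 7.0, 8.31, 118.9),
        ResidueSignal(75, 45.0, 5.0, 8.22, 120.2),
        ResidueSignal(76, 70.0, 8.0, 8.10, 122.8),
        ResidueSignal(77, 50.0, 6.0, 8.27, 119.6),
        ResidueSignal(87, 65.0, 8.0, 8.15, 120.9),
        ResidueSignal(88, 80.0, 9.0, 8.08, 121.1),
        ResidueSignal(89, 60.0, 7.0, 8.19, 119.3),
    ]
    flat_rng = np.random.default_rng(12345)  # fixed layout, independent of noise seed
    flat = [
        ResidueSignal(res, 0.0, 0.0,
                      float(8.0 + 0.5 * flat_rng.random()),
                      float(115.0 + 10.0 * flat_rng.random()))
        for res in range(22, 58) if res not in (36, 47)  # prolines lack amide peaks
    ] + [ResidueSignal(res, 0.0, 0.0, 8.3, 118.0) for res in (92, 96, 100, 104)]
    return TitrationSimSpec(residues=responsive + flat, kd_true_mM=kd_true_mM,
                            noise_sd_h=noise_sd_h, noise_sd_n=noise_sd_n,
                            seed=seed)


# ---------------------------------------------------------------------------
# two-state distance trajectories

@dataclass
class TwoStateTrajectorySpec:
    """Two-state (compact/extended) Gaussian distance dynamics.

    ``pair_params`` maps a pair label to ``((mean_c, sd_c), (mean_e, sd_e))``
    in Å.  State switching is a discrete-frame two-state Markov chain; the
    dwell parameters are the expected residence times in frames.
    """

    pair_params: Mapping[str, tuple[tuple[float, float], tuple[float, float]]]
    dwell_compact: float = 500.0
    dwell_extended: float = 500.0
    frame_interval_ps: float = 2.0
    n_frames: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dwell_compact < 1 or self.dwell_extended < 1:
            raise ValueError("dwell must be >= 1 frame")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame interval must be > 0")
        for label, (c, e) in self.pair_params.items():
            for mean, sd in (c, e):
                if mean <= 0:
                    raise ValueError(f"pair {label}: state means must be > 0")
                if sd < 0:
                    raise ValueError(f"pair {label}: state SDs must be >= 0")


def _markov_states(n: int, dwell_c: float, dwell_e: float,
                   rng: np.random.Generator) -> np.ndarray:
    """0/1 state sequence with geometric dwell times (0 = compact)."""
    p_leave = (1.0 / dwell_c, 1.0 / dwell_e)
    pi_compact = dwell_c / (dwell_c + dwell_e)   # stationary occupancy
    state = 0 if rng.random() < pi_compact else 1
    out = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        run = min(int(rng.geometric(p_leave[state])), n - i)
        out[i:i + run] = state
        i += run
        state = 1 - state
    return out


def simulate_two_state_trajectory(spec: TwoStateTrajectorySpec) -> DistanceStateSeries:
    """Sample a labelled two-state distance trajectory.

    Per frame, every pair draws from its active state's Gaussian; draws are
    truncated at a small positive floor so distances stay physical.  The
    hidden state sequence is returned as ``true_states``.
    """
    rng = np.random.default_rng(spec.seed)
    states = _markov_states(spec.n_frames, spec.dwell_compact,
                            spec.dwell_extended, rng)
    dist = {}
    for label, (c, e) in spec.pair_params.items():
        means = np.where(states == 0, c[0], e[0])
        sds = np.where(states == 0, c[1], e[1])
        d = means + sds * rng.standard_normal(spec.n_frames)
        dist[label] = np.clip(d, 1e-3, None)
    times = np.arange(spec.n_frames) * spec.frame_interval_ps
    return DistanceStateSeries(
        times_ps=times,
        distances=pd.DataFrame(dist),
        true_states=np.where(states == 0, "compact", "extended"),
    )


def fig9_printed_spec(n_frames: int = 200_000, seed: int = 0) -> TwoStateTrajectorySpec:
    """Trajectory parameterised directly by the printed per-pair statistics.

    Each pair uses the same Gaussian in both states (16.5 +/- 2.3 Å for
    W60-W76, 20.5 +/- 5.5 Å for W60-Y88, 19.6 +/- 4.0 Å for W76-Y88), so
    the marginal distributions reproduce the printed values exactly and the
    sample mean obeys the i.i.d. SD/sqrt(n) law.
    """
    params = {
        "W60-W76": ((16.5, 2.3), (16.5, 2.3)),
        "W60-Y88": ((20.5, 5.5), (20.5, 5.5)),
        "W76-Y88": ((19.6, 4.0), (19.6, 4.0)),
    }
    return TwoStateTrajectorySpec(pair_params=params, n_frames=n_frames, seed=seed)


def default_two_state_spec(n_frames: int = 50_000, seed: int = 0,
                           dwell_compact: float = 400.0,
                           dwell_extended: float = 600.0) -> TwoStateTrajectorySpec:
    """A resolvable compact/extended parameterisation for recovery tests.

    The Y88 pairs switch between compact (~15 Å) and extended (~25 Å) states
    symmetric about the 20 Å cutoff, about 4 pooled SDs apart, while W60-W76
    stays in its narrow single range.  Dwells of 400/600 frames (0.8/1.2 ns
    at 2 ps spacing) give nanosecond-scale state stability and a compact
    occupancy of 0.4.
    """
    params = {
        "W60-W76": ((16.5, 2.3), (16.5, 2.3)),
        "W60-Y88": ((15.0, 2.5), (25.0, 2.5)),
        "W76-Y88": ((14.5, 2.0), (24.5, 2.0)),
    }
    return TwoStateTrajectorySpec(pair_params=params, n_frames=n_frames,
                                  dwell_compact=dwell_compact,
                                  dwell_extended=dwell_extended, seed=seed)


# ---------------------------------------------------------------------------
# combinatorial SMILES libraries

@dataclass
class LibrarySimSpec:
    """Combinatorial scaffold x substituent library with decoys.

    Substituents are SMILES fragments attached via their first atom to a
    deterministically chosen aromatic CH of the scaffold; all defaults
    attach through carbon so that every member of a scaffold shares the
    same alpha-preserved scaffold (required for frequency ground truth).
    """

    scaffolds: Sequence[str] = (
        "c1ccc2ccccc2c1",            # naphthalene
        "c1ccc2ncccc2c1",            # quinoline
        "c1ccc(-c2ccccc2)cc1",       # biphenyl
        "c1ccc2c(c1)[nH]c1ccccc12",  # carbazole
    )
    substituents: Sequence[str] = ("C", "CC", "CCC", "CCO", "CC(C)C", "CCN", "CC#N", "CCOC")
    multiplicity: Mapping[str, int] = field(default_factory=dict)
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must be in [0, 1)")
        for smi in self.scaffolds:
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"unparseable scaffold SMILES: {smi!r}")
        for smi in self.substituents:
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"unparseable substituent SMILES: {smi!r}")
        for smi, mult in self.multiplicity.items():
            if mult < 0:
                raise ValueError(f"multiplicity must be >= 0 (scaffold {smi!r})")


@dataclass
class SimulatedLibrary:
    """Generated library entries plus ground truth."""

    entries: list[tuple[str, str]]          # (id, smiles)
    hts_frequency: dict[str, int]           # alpha-scaffold SMILES -> count
    truth: pd.DataFrame                     # per entry: scaffold, decoy flags, verdict


_DECOY_POOL: tuple[tuple[str, str], ...] = (
    ("invalid", "C1CC(C"),                # unbalanced ring/parenthesis
    ("inorganic", "[SiH3]c1ccccc1"),
    ("isotope", "[13CH3]c1ccccc1"),
    ("invalid", "c1ccccc1)("),
    ("inorganic", "CC[Se]CC"),
    ("isotope", "[2H]OCC"),
)


def _attach(scaffold: Chem.Mol, substituent_smiles: str) -> str:
    """Bond a substituent's first atom to the first aromatic CH of the scaffold."""
    sub = Chem.MolFromSmiles(substituent_smiles)
    if sub is None:
        raise ValueError(f"unparseable substituent SMILES: {substituent_smiles!r}")
    anchor = None
    for atom in scaffold.GetAtoms():
        if atom.GetIsAromatic() and atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() > 0:
            anchor = atom.GetIdx()
            break
    if anchor is None:
        raise ValueError("scaffold has no aromatic CH attachment point")
    combo = Chem.RWMol(Chem.CombineMols(scaffold, sub))
    combo.AddBond(anchor, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def simulate_library(spec: LibrarySimSpec) -> SimulatedLibrary:
    """Emit a combinatorial library with exact scaffold multiplicities.

    Member ``j`` of a scaffold combines substituent ``j mod k`` with a
    ``j // k``-methylene spacer, so members are distinct yet share one
    alpha-preserved scaffold.  The mock HTS table reports that scaffold with
    a count equal to the multiplicity (the mock collection is the library
    itself).  Decoys are appended deterministically so that they make up
    ``decoy_fraction`` of the final library; ground truth flags them.
    """
    from .curation import murcko_scaffold  # deferred: curation imports rdkit heavily

    multiplicity = dict(spec.multiplicity) or {s: 4 for s in spec.scaffolds}
    entries: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    hts: dict[str, int] = {}
    k = len(spec.substituents)
    for s_idx, scaffold_smi in enumerate(spec.scaffolds):
        mult = multiplicity.get(scaffold_smi, 0)
        if mult == 0:
            continue
        scaffold = Chem.MolFromSmiles(scaffold_smi)
        member_smiles: list[str] = []
        for j in range(mult):
            if k == 0:
                member_smiles.append(Chem.MolToSmiles(scaffold))
            else:
                sub = "C" * (j // k) + spec.substituents[j % k]
                member_smiles.append(_attach(scaffold, sub))
        alpha_scaffold = murcko_scaffold(Chem.MolFromSmiles(member_smiles[0]),
                                         keep_alpha=True)
        hts[alpha_scaffold] = mult
        for j, smi in enumerate(member_smiles):
            mol_id = f"S{s_idx}_{j}"
            entries.append((mol_id, smi))
            truth_rows.append({
                "id": mol_id, "smiles": smi, "scaffold": alpha_scaffold,
                "is_decoy": False, "decoy_kind": "",
                "passes_frequency": mult >= 8,
            })
    n_members = len(entries)
    n_decoys = int(round(spec.decoy_fraction / (1.0 - spec.decoy_fraction) * n_members))
    for d in range(n_decoys):
        kind, smi = _DECOY_POOL[d % len(_DECOY_POOL)]
        mol_id = f"D{d}"
        entries.append((mol_id, smi))
        truth_rows.append({
            "id": mol_id, "smiles": smi, "scaffold": "",
            "is_decoy": True, "decoy_kind": kind, "passes_frequency": False,
        })
    # deterministic shuffle so decoys are interleaved like real contamination
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order]).set_index("id")
    return SimulatedLibrary(entries=entries, hts_frequency=hts, truth=truth)


def default_library_spec(seed: int = 0) -> LibrarySimSpec:
    """Default: two abundant scaffolds (pass the frequency filter) and two
    rare ones (fail), no decoys."""
    spec = LibrarySimSpec(seed=seed)
    return LibrarySimSpec(
        scaffolds=spec.scaffolds,
        substituents=spec.substituents,
        multiplicity={spec.scaffolds[0]: 8, spec.scaffolds[1]: 10,
                      spec.scaffolds[2]: 7, spec.scaffolds[3]: 3},
        seed=seed,
    )
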