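"""MD trajectory distance analysis for disordered-protein state classification.

Transient clustering of the three aromatic residues W60, W76 and Y88 of
p27-D2 creates the small-molecule binding sites, and shows up in MD
trajectories as two-state (compact/extended) dynamics of the pairwise
Cbeta-Cbeta distances.  This module extracts those distances from a
multi-model PDB (or a precomputed distance table), forms non-overlapping
window averages, classifies each frame, summarises the distance
distributions, and measures contact co-occurrence between pairs.

Classification rules (strict ``<`` at the cutoff, default 20 Å):

* ``"y88"`` (default) — compact iff Y88 is within the cutoff of either W
  residue, i.e. ``min(d(W60,Y88), d(W76,Y88)) < cutoff``.  The W60-W76
  distance sits near 16.5 Å throughout, so including it would label nearly
  every frame compact and erase the two-state split.
* ``"any"`` — the literal reading: compact iff any of the three pairs is
  within the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DistanceStateSeries",
    "StateConfig",
    "DistanceStats",
    "PAIR_LABELS",
    "extract_distances",
    "read_distance_csv",
    "write_distance_csv",
    "window_average",
    "classify_frames",
    "distance_statistics",
    "contact_cooccurrence",
]

#: Canonical residue-pair labels for the three aromatic-cluster distances.
PAIR_LABELS: tuple[str, str, str] = ("W60-W76", "W60-Y88", "W76-Y88")

_RESIDUE_NAMES = {60: "W60", 76: "W76", 88: "Y88"}


@dataclass
class StateConfig:
    """Parameters of the distance extraction and state classification."""

    pairs: tuple[tuple[int, int], ...] = ((60, 76), (60, 88), (76, 88))
    atom_name: str = "CB"
    cutoff: float = 20.0          # Å, strict "<" for compact
    window_ns: float = 1.0        # block-average window
    stride_ps: float = 2.0        # frame spacing
    compact_rule: str = "y88"     # or "any"
    residue_offset: int = 0       # add to construct numbering to reach p27 numbering

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.window_ns * 1000.0 < self.stride_ps:
            raise ValueError("averaging window must be >= frame spacing")
        if self.compact_rule not in ("y88", "any"):
            raise ValueError("compact_rule must be 'y88' or 'any'")

    def pair_label(self, r1: int, r2: int) -> str:
        a, b = sorted((r1, r2))
        return f"{_RESIDUE_NAMES.get(a, a)}-{_RESIDUE_NAMES.get(b, b)}"

    @property
    def pair_labels(self) -> list[str]:
        return [self.pair_label(*p) for p in self.pairs]


@dataclass
class DistanceStateSeries:
    """Labelled pairwise distances over time, plus optional state labels.

    ``distances``: DataFrame, rows = frames, columns = pair labels (Å).
    ``true_states`` carries simulator ground truth when available;
    ``states`` holds classifier output ("compact"/"extended").
    """

    times_ps: np.ndarray
    distances: pd.DataFrame
    states: np.ndarray | None = None
    true_states: np.ndarray | None = None
    occupancy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if len(self.times_ps) != len(self.distances):
            raise ValueError("times and distance table must have equal length")
        if (self.distances.to_numpy() <= 0).any():
            raise ValueError("distances must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.distances)

    @property
    def span_ns(self) -> float:
        """Total simulated span implied by the frame spacing."""
        if self.n_frames < 2:
            return 0.0
        dt = self.times_ps[1] - self.times_ps[0]
        return self.n_frames * dt / 1000.0


def extract_distances(trajectory, config: StateConfig | None = None) -> DistanceStateSeries:
    """Pairwise atom distances per frame from a multi-model PDB.

    ``trajectory`` is a path to a multi-model PDB (MODEL/ENDMDL records) or
    an already-built ``MDAnalysis.Universe``.  Each configured residue must
    provide exactly one atom named ``config.atom_name`` in every frame;
    otherwise an error names the offending residue.
    """
    import MDAnalysis as mda

    config = config or StateConfig()
    u = trajectory if isinstance(trajectory, mda.Universe) else mda.Universe(str(trajectory))
    sel = {}
    residues = sorted({r for pair in config.pairs for r in pair})
    for res in residues:
        resid = res - config.residue_offset
        ag = u.select_atoms(f"resid {resid} and name {config.atom_name}")
        if len(ag) != 1:
            raise ValueError(
                f"residue {res} (resid {resid}): expected exactly one "
                f"{config.atom_name} atom, found {len(ag)}"
            )
        sel[res] = ag
    rows = []
    for _ts in u.trajectory:
        pos = {res: sel[res].positions[0] for res in residues}
        rows.append([float(np.linalg.norm(pos[a] - pos[b])) for a, b in config.pairs])
    dist = pd.DataFrame(rows, columns=config.pair_labels)
    degenerate = (dist.to_numpy() < 1e-6).any()
    if degenerate:
        warnings.warn("degenerate (near-zero) distances found in trajectory",
                      stacklevel=2)
        dist = dist.clip(lower=1e-6)
    times = np.arange(len(dist)) * config.stride_ps
    return DistanceStateSeries(times_ps=times, distances=dist)


def read_distance_csv(path: str | Path) -> DistanceStateSeries:
    """Read a precomputed distance table: ``time_ps, d_W60_W76, ...``."""
    df = pd.read_csv(path)
    if "time_ps" not in df.columns:
        raise ValueError("distance CSV must have a 'time_ps' column")
    dcols = [c for c in df.columns if c.startswith("d_")]
    if not dcols:
        raise ValueError("distance CSV has no 'd_<pair>' columns")
    dist = df[dcols].copy()
    dist.columns = [c[2:].replace("_", "-") for c in dcols]
    return DistanceStateSeries(times_ps=df["time_ps"].to_numpy(dtype=float),
                               distances=dist.reset_index(drop=True))


def write_distance_csv(series: DistanceStateSeries, path: str | Path) -> None:
    out = pd.DataFrame({"time_ps": series.times_ps})
    for col in series.distances.columns:
        out[f"d_{col.replace('-', '_')}"] = series.distances[col].to_numpy()
    out.to_csv(path, index=False)


def window_average(series: DistanceStateSeries,
                   window_ns: float = 1.0) -> tuple[pd.DataFrame, bool]:
    """Non-overlapping block means of every distance trace.

    Returns (DataFrame indexed by block start time in ps, flag indicating a
    trailing partial block, which is averaged over its available frames).
    """
    if series.n_frames < 2:
        raise ValueError("need >= 2 frames to window-average")
    dt = series.times_ps[1] - series.times_ps[0]
    if window_ns * 1000.0 < dt:
        raise ValueError("window must be >= frame spacing")
    block = max(int(round(window_ns * 1000.0 / dt)), 1)
    n = series.n_frames
    idx = np.arange(n) // block
    means = series.distances.groupby(idx).mean()
    means.index = pd.Index(series.times_ps[::block][: len(means)], name="block_start_ps")
    partial = bool(n % block)
    if partial:
        warnings.warn(
            f"trailing partial block of {n % block} frame(s) averaged", stacklevel=2)
    return means, partial


def classify_frames(series: DistanceStateSeries,
                    config: StateConfig | None = None) -> DistanceStateSeries:
    """Label every frame compact/extended and compute occupancies.

    Returns a new series with ``states`` filled and ``occupancy`` giving the
    fraction of frames per state.  See the module docstring for the two
    rules; the cutoff comparison is strict (exactly-at-cutoff is extended).
    """
    config = config or StateConfig()
    cols = series.distances.columns
    if config.compact_rule == "y88":
        needed = [c for c in cols if "Y88" in c]
        if len(needed) < 2:
            raise ValueError("the 'y88' rule needs both W-Y88 distance pairs")
        crit = series.distances[needed].min(axis=1)
    else:
        crit = series.distances.min(axis=1)
    compact = (crit < config.cutoff).to_numpy()
    states = np.where(compact, "compact", "extended")
    occ = {
        "compact": float(compact.mean()),
        "extended": float(1.0 - compact.mean()),
    }
    return DistanceStateSeries(
        times_ps=series.times_ps,
        distances=series.distances,
        states=states,
        true_states=series.true_states,
        occupancy=occ,
    )


@dataclass
class DistanceStats:
    """Distribution summary of labelled distance traces."""

    summary: pd.DataFrame                      # per pair: mean, sd, n
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # pair -> (counts, edges)
    state_summary: pd.DataFrame | None         # per pair x state mean/sd/occupancy


def distance_statistics(series: DistanceStateSeries,
                        bin_width: float = 0.5,
                        bin_range: tuple[float, float] = (0.0, 50.0)) -> DistanceStats:
    """Per-pair sample mean/SD, fixed-bin histograms and a two-component
    summary (per-state means and occupancies) when state labels are present.
    """
    if series.n_frames < 2:
        raise ValueError("need >= 2 frames for distance statistics")
    edges = np.arange(bin_range[0], bin_range[1] + bin_width / 2, bin_width)
    summary = pd.DataFrame({
        "mean": series.distances.mean(),
        "sd": series.distances.std(ddof=1),
        "n": series.n_frames,
    })
    histograms = {
        col: np.histogram(series.distances[col].to_numpy(), bins=edges)
        for col in series.distances.columns
    }
    state_summary = None
    if series.states is not None:
        rows = []
        states = pd.Series(series.states, index=series.distances.index)
        for state, grp in series.distances.groupby(states):
            for col in series.distances.columns:
                rows.append({
                    "pair": col, "state": state,
                    "mean": grp[col].mean(),
                    "sd": grp[col].std(ddof=1) if len(grp) > 1 else 0.0,
                    "occupancy": len(grp) / series.n_frames,
                })
        state_summary = pd.DataFrame(rows).set_index(["pair", "state"])
    return DistanceStats(summary=summary, histograms=histograms,
                         state_summary=state_summary)


def contact_cooccurrence(series: DistanceStateSeries,
                         cutoff: float = 20.0) -> dict:
    """Pairwise contact co-occurrence and distance-trace correlations.

    A pair is "in contact" in a frame when its distance is below ``cutoff``.
    Returns a dict with ``marginal`` (per-pair contact fraction),
    ``cooccurrence`` (pair-of-pairs fraction of frames with both in
    contact), ``triple_fraction`` (all pairs simultaneously in contact) and
    ``correlation`` (Pearson, NaN for constant traces).
    """
    if series.distances.shape[1] < 2:
        raise ValueError("need >= 2 distance pairs")
    contacts = series.distances < cutoff
    cols = list(series.distances.columns)
    marginal = contacts.mean()
    co = pd.DataFrame(index=cols, columns=cols, dtype=float)
    for a in cols:
        for b in cols:
            co.loc[a, b] = float((contacts[a] & contacts[b]).mean())
    corr = pd.DataFrame(index=cols, columns=cols, dtype=float)
    arr = series.distances.to_numpy()
    sds = arr.std(axis=0)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if sds[i] == 0 or sds[j] == 0:
                corr.loc[a, b] = np.nan  # undefined for a constant trace
            else:
                corr.loc[a, b] = float(np.corrcoef(arr[:, i], arr[:, j])[0, 1])
    return {
        "marginal": marginal,
        "cooccurrence": co,
        "triple_fraction": float(contacts.all(axis=1).mean()),
        "correlation": corr,
    }
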