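"""Fragment-library curation: validity filtering, Murcko scaffolds with alpha
atoms, a scaffold filter cascade, complexity ranking, and Rule-of-Three checks.

The curation pipeline mirrors how screening libraries are assembled from
commercial fragment collections:

1. sanitise — drop invalid structures, molecules with non-organic elements,
   and isotope-labelled entries;
2. abstract each molecule to its Murcko scaffold (ring systems plus linkers),
   optionally keeping *alpha atoms* — heavy atoms bonded directly to the
   scaffold;
3. filter scaffolds: no reactive (REOS) substructures, <= 3 rotatable bonds,
   >= 10 heavy atoms, >= 1 ring, more than one ring substitution for
   single-ring systems, and an HTS-collection scaffold frequency >= 8;
4. rank member molecules by a molecular-complexity score (descending) for
   purchase prioritisation;
5. check the Rule of Three (MW < 300, HBD <= 3, HBA <= 3, clogP <= 3) and
   profile the final library (mean +/- SD of the physicochemical properties).

RDKit supplies all descriptors and substructure matching; the
alpha-preserving scaffold abstraction is implemented here by graph pruning
since the stock Murcko decomposition discards substituent attachment atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "CompoundRecord",
    "ScaffoldRecord",
    "FilterConfig",
    "DEFAULT_REOS_SMARTS",
    "ORGANIC_ELEMENTS",
    "sanitize_library",
    "murcko_scaffold",
    "build_scaffold_records",
    "apply_scaffold_filters",
    "oprea_complexity",
    "rank_by_complexity",
    "check_ro3",
    "profile_library",
    "read_smiles_file",
    "read_sdf",
    "read_frequency_table",
    "curate_library",
]

logger = logging.getLogger(__name__)

#: Atomic numbers accepted as "organic" (H, B, C, N, O, F, P, S, Cl, Br, I).
ORGANIC_ELEMENTS = frozenset({1, 5, 6, 7, 8, 9, 15, 16, 17, 35, 53})

#: Default reactive-substructure (REOS-style) exclusion patterns.  The
#: published filter sets are cited, not listed, so this is a documented,
#: user-overridable default covering the classic electrophile/unstable
#: classes.
DEFAULT_REOS_SMARTS: dict[str, str] = {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
    "alkyl_halide": "[CX4][Cl,Br,I]",
    "peroxide": "[OX2][OX2]",
    "epoxide_aziridine": "[C,N]1[C][O,N]1",
    "anhydride": "[CX3](=O)[OX2][CX3](=O)",
    "isocyanate": "[NX2]=[CX2]=[OX1,SX1]",
    "azide": "[NX2]=[NX2+]=[NX1-]",
    "diazonium": "[NX2+]#[NX1]",
    "thiol": "[SX2H]",
    "nitroso": "[NX2]=[OX1]",
    "hydrazine": "[NX3H2][NX3H1,NX3H2]",
    "sulfonyl_halide": "[SX4](=O)(=O)[F,Cl,Br,I]",
}


@dataclass
class CompoundRecord:
    """One library molecule with its physicochemical profile and verdicts."""

    id: str
    smiles: str
    mol: Chem.Mol
    mw: float
    heavy_atoms: int
    clogp: float
    psa: float
    hba: int
    hbd: int
    rotatable_bonds: int
    ring_count: int
    scaffold_id: str | None = None
    complexity: float | None = None
    verdicts: dict[str, bool] = field(default_factory=dict)


@dataclass
class ScaffoldRecord:
    """A canonical scaffold shared by one or more library members."""

    smiles: str
    members: list[str]
    hts_frequency: int = 0
    rotatable_bonds: int = 0
    heavy_atoms: int = 0
    ring_count: int = 0
    ring_substitutions: int = 0
    verdicts: dict[str, bool] = field(default_factory=dict)
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a scaffold record must have at least one member")
        if self.hts_frequency < 0:
            raise ValueError("hts_frequency must be >= 0")


@dataclass
class FilterConfig:
    """Thresholds for the scaffold filter cascade and the Rule of Three."""

    reactive_smarts: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REOS_SMARTS))
    max_rotatable_bonds: int = 3
    min_heavy_atoms: int = 10
    min_rings: int = 1
    min_ring_substitutions_single_ring: int = 2   # "> 1" for single rings
    min_hts_frequency: int = 8
    ro3_max_mw: float = 300.0          # strict "<"
    ro3_max_hbd: int = 3
    ro3_max_hba: int = 3
    ro3_max_clogp: float = 3.0
    keep_alpha: bool = True
    filter_level: str = "scaffold"     # or "molecule": thresholds on parents

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _make_record(mol_id: str, mol: Chem.Mol) -> CompoundRecord:
    return CompoundRecord(
        id=mol_id,
        smiles=Chem.MolToSmiles(mol),
        mol=mol,
        mw=Descriptors.MolWt(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        clogp=Crippen.MolLogP(mol),
        psa=Descriptors.TPSA(mol),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        ring_count=rdMolDescriptors.CalcNumRings(mol),
    )


def sanitize_library(
    entries: Iterable[tuple[str, str] | Chem.Mol],
) -> tuple[list[CompoundRecord], list[tuple[str, str]]]:
    """Split raw entries into valid compound records and tagged rejects.

    ``entries`` are ``(id, smiles)`` pairs or pre-parsed RDKit molecules
    (e.g. from an SDF).  Rejects carry one of the reasons ``"invalid"``,
    ``"inorganic"`` or ``"isotope"``.  An empty input yields empty outputs.
    """
    valid: list[CompoundRecord] = []
    rejects: list[tuple[str, str]] = []
    for i, entry in enumerate(entries):
        if entry is None:  # e.g. an unparseable SDF block
            rejects.append((f"mol{i}", "invalid"))
            continue
        if isinstance(entry, Chem.Mol):
            mol: Chem.Mol | None = entry
            mol_id = (mol.GetProp("_Name") if mol is not None and mol.HasProp("_Name")
                      else f"mol{i}")
        else:
            mol_id, smi = entry
            mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rejects.append((mol_id, "invalid"))
            continue
        if any(a.GetAtomicNum() not in ORGANIC_ELEMENTS for a in mol.GetAtoms()):
            rejects.append((mol_id, "inorganic"))
            continue
        if any(a.GetIsotope() != 0 for a in mol.GetAtoms()):
            rejects.append((mol_id, "isotope"))
            continue
        valid.append(_make_record(mol_id, mol))
    return valid, rejects


def _scaffold_atom_indices(mol: Chem.Mol, keep_alpha: bool) -> set[int]:
    """Atom indices of the Murcko scaffold (+ alpha atoms when requested).

    The scaffold is obtained by iteratively pruning terminal heavy atoms that
    are not in rings; what survives is exactly the ring systems plus the
    linkers between them.  Alpha atoms are heavy atoms directly bonded to a
    surviving atom.
    """
    keep = {a.GetIdx() for a in mol.GetAtoms()}
    ring_info = mol.GetRingInfo()
    if ring_info.NumRings() == 0:
        return set()
    changed = True
    while changed:
        changed = False
        for idx in list(keep):
            atom = mol.GetAtomWithIdx(idx)
            if atom.IsInRing():
                continue
            degree = sum(1 for n in atom.GetNeighbors() if n.GetIdx() in keep)
            if degree <= 1:
                keep.discard(idx)
                changed = True
    if keep_alpha:
        alpha = set()
        for idx in keep:
            for n in mol.GetAtomWithIdx(idx).GetNeighbors():
                if n.GetIdx() not in keep:
                    alpha.add(n.GetIdx())
        keep |= alpha
    return keep


def murcko_scaffold(mol_or_record: Chem.Mol | CompoundRecord,
                    keep_alpha: bool = True) -> str:
    """Canonical SMILES of the molecule's Murcko scaffold.

    With ``keep_alpha`` the atoms directly bonded to the ring/linker
    framework are retained (so e.g. ethylbenzene maps to the toluene
    skeleton, not bare benzene), which preserves substitution patterns when
    counting scaffold frequencies.  Acyclic molecules yield ``""``.
    """
    mol = mol_or_record.mol if isinstance(mol_or_record, CompoundRecord) else mol_or_record
    keep = _scaffold_atom_indices(mol, keep_alpha)
    if not keep:
        return ""
    rw = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep),
                      reverse=True):
        rw.RemoveAtom(idx)
    scaffold = rw.GetMol()
    Chem.SanitizeMol(scaffold)
    return Chem.MolToSmiles(scaffold)


def _ring_substitutions(scaffold: Chem.Mol) -> int:
    """Attachment points: bonds from a ring atom to a non-ring heavy atom."""
    count = 0
    for bond in scaffold.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.IsInRing() != b.IsInRing():
            count += 1
    return count


def build_scaffold_records(
    records: Sequence[CompoundRecord],
    keep_alpha: bool = True,
) -> dict[str, ScaffoldRecord]:
    """Group compound records by canonical scaffold SMILES.

    Annotates each record's ``scaffold_id`` in place.  Acyclic molecules
    (empty scaffold) are grouped under ``""``.
    """
    groups: dict[str, list[str]] = {}
    for rec in records:
        smi = murcko_scaffold(rec, keep_alpha=keep_alpha)
        rec.scaffold_id = smi
        groups.setdefault(smi, []).append(rec.id)
    out: dict[str, ScaffoldRecord] = {}
    for smi in sorted(groups):
        members = sorted(groups[smi])
        if smi == "":
            out[smi] = ScaffoldRecord(smiles="", members=members)
            continue
        mol = Chem.MolFromSmiles(smi)
        out[smi] = ScaffoldRecord(
            smiles=smi,
            members=members,
            rotatable_bonds=Lipinski.NumRotatableBonds(mol),
            heavy_atoms=mol.GetNumHeavyAtoms(),
            ring_count=rdMolDescriptors.CalcNumRings(mol),
            ring_substitutions=_ring_substitutions(mol),
        )
    return out


def _count_reactive(mol: Chem.Mol, patterns: Mapping[str, str]) -> list[str]:
    hits = []
    for name, smarts in patterns.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for reactive pattern {name!r}: {smarts!r}")
        if mol.HasSubstructMatch(patt):
            hits.append(name)
    return hits


def apply_scaffold_filters(
    scaffolds: Mapping[str, ScaffoldRecord] | Sequence[ScaffoldRecord],
    config: FilterConfig,
    hts_frequency: Mapping[str, int],
) -> list[ScaffoldRecord]:
    """Run the scaffold filter cascade; return passing scaffolds.

    A scaffold passes iff it has no reactive-substructure match, at most 3
    rotatable bonds, at least 10 heavy atoms, at least one ring, more than
    one ring substitution when it is a single-ring system, and an HTS
    frequency of at least 8 (defaults; all thresholds from ``config``).
    Scaffolds absent from the frequency table get frequency 0 and fail that
    criterion.  Verdicts and failure reasons are recorded on every record.
    """
    if isinstance(scaffolds, Mapping):
        records = list(scaffolds.values())
    else:
        records = list(scaffolds)
    passing: list[ScaffoldRecord] = []
    for rec in sorted(records, key=lambda r: r.smiles):
        rec.failure_reasons = []
        if rec.smiles == "":
            rec.verdicts = {"rings": False}
            rec.failure_reasons = ["rings"]
            continue
        if rec.smiles not in hts_frequency:
            logger.warning("scaffold %s absent from HTS frequency table; "
                           "frequency set to 0", rec.smiles)
        rec.hts_frequency = int(hts_frequency.get(rec.smiles, 0))
        mol = Chem.MolFromSmiles(rec.smiles)
        reactive_hits = _count_reactive(mol, config.reactive_smarts)
        v = {
            "reactive": len(reactive_hits) == 0,
            "rotatable_bonds": rec.rotatable_bonds <= config.max_rotatable_bonds,
            "heavy_atoms": rec.heavy_atoms >= config.min_heavy_atoms,
            "rings": rec.ring_count >= config.min_rings,
            "ring_substitutions": (
                rec.ring_count > 1
                or rec.ring_substitutions >= config.min_ring_substitutions_single_ring
            ),
            "hts_frequency": rec.hts_frequency >= config.min_hts_frequency,
        }
        rec.verdicts = v
        rec.failure_reasons = [k for k, ok in v.items() if not ok]
        if reactive_hits:
            rec.failure_reasons.extend(f"reactive:{h}" for h in reactive_hits)
        if all(v.values()):
            passing.append(rec)
    return passing


#: Default weights for the additive complexity score.
DEFAULT_COMPLEXITY_WEIGHTS: dict[str, float] = {
    "ring": 2.0,
    "ring_fusion": 1.5,
    "heteroatom": 1.0,
    "stereocenter": 2.0,
    "branch": 0.5,
}


def oprea_complexity(mol: Chem.Mol,
                     weights: Mapping[str, float] | None = None) -> float:
    """Additive molecular-complexity score used to prioritise purchases.

    score = w_ring * n_rings + w_fusion * n_ring_fusion_bonds
          + w_het * n_heteroatoms + w_stereo * n_stereocenters
          + w_branch * n_branch_atoms

    where branch atoms have heavy-atom degree >= 3 and stereocentres include
    unassigned ones.  Rankings, not absolute values, drive the pipeline, and
    the weights are configurable; any scorer with the same signature can be
    passed to :func:`rank_by_complexity` instead.
    """
    w = dict(DEFAULT_COMPLEXITY_WEIGHTS)
    if weights:
        w.update(weights)
    ri = mol.GetRingInfo()
    n_rings = ri.NumRings()
    n_fusion = sum(1 for b in mol.GetBonds() if ri.NumBondRings(b.GetIdx()) > 1)
    n_het = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    n_stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True,
                                             useLegacyImplementation=False))
    n_branch = sum(1 for a in mol.GetAtoms() if a.GetDegree() >= 3)
    return (w["ring"] * n_rings + w["ring_fusion"] * n_fusion
            + w["heteroatom"] * n_het + w["stereocenter"] * n_stereo
            + w["branch"] * n_branch)


def rank_by_complexity(
    records: Sequence[CompoundRecord],
    scorer: Callable[[Chem.Mol], float] = oprea_complexity,
) -> list[CompoundRecord]:
    """Stable descending sort by complexity; ties broken by id.

    Scores are computed with ``scorer`` where a record has none cached.
    """
    for rec in records:
        if rec.complexity is None:
            rec.complexity = scorer(rec.mol)
    return sorted(records, key=lambda r: (-r.complexity, r.id))


def check_ro3(record: CompoundRecord,
              config: FilterConfig | None = None) -> tuple[bool, dict[str, bool | str]]:
    """Rule-of-Three check: MW < 300, HBD <= 3, HBA <= 3, clogP <= 3.

    Returns (overall pass, per-criterion detail).  A missing property fails
    with the detail ``"uncomputed"``.
    """
    cfg = config or FilterConfig()
    checks: dict[str, tuple[float | None, Callable[[float], bool]]] = {
        "mw": (record.mw, lambda v: v < cfg.ro3_max_mw),
        "hbd": (record.hbd, lambda v: v <= cfg.ro3_max_hbd),
        "hba": (record.hba, lambda v: v <= cfg.ro3_max_hba),
        "clogp": (record.clogp, lambda v: v <= cfg.ro3_max_clogp),
    }
    detail: dict[str, bool | str] = {}
    for name, (value, ok) in checks.items():
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            detail[name] = "uncomputed"
        else:
            detail[name] = bool(ok(value))
    passed = all(v is True for v in detail.values())
    record.verdicts["ro3"] = passed
    return passed, detail


_PROFILE_PROPS = ("mw", "heavy_atoms", "clogp", "psa", "hba", "hbd")


def profile_library(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Mean and sample SD (n-1) of the library's physicochemical properties.

    A singleton library reports SD 0 with a warning.
    """
    if not records:
        raise ValueError("cannot profile an empty library")
    df = pd.DataFrame({p: [getattr(r, p) for r in records] for p in _PROFILE_PROPS})
    if len(records) == 1:
        warnings.warn("profiling a single molecule: SD reported as 0", stacklevel=2)
        sd = pd.Series(0.0, index=df.columns)
    else:
        sd = df.std(ddof=1)
    return pd.DataFrame({"mean": df.mean(), "sd": sd})


# ---------------------------------------------------------------------------
# file I/O and the end-to-end pipeline

def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, id after whitespace."""
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            entries.append((mol_id, smi))
    return entries


def read_sdf(path: str | Path) -> list[Chem.Mol]:
    """Read an SDF; unparseable entries come back as None-free list later."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    return [m for m in supplier]


def read_frequency_table(path: str | Path) -> dict[str, int]:
    """Two-column CSV: canonical scaffold SMILES, count in the HTS library."""
    df = pd.read_csv(path, header=None, names=["smiles", "count"], comment="#",
                     skip_blank_lines=True)
    if df.iloc[0]["smiles"] in ("smiles", "scaffold", "scaffold_smiles"):
        df = df.iloc[1:]
    return {str(s): int(c) for s, c in zip(df["smiles"], df["count"])}


def curate_library(
    entries: Iterable[tuple[str, str] | Chem.Mol],
    hts_frequency: Mapping[str, int],
    config: FilterConfig | None = None,
) -> dict:
    """Run the full curation pipeline.

    Returns a dict with ``records`` (ranked members of passing scaffolds),
    ``rejects``, ``scaffolds`` (all, with verdicts), ``passing_scaffolds``
    and ``profile``.  With ``config.filter_level == "molecule"`` the
    rotatable-bond and heavy-atom thresholds are evaluated on the parent
    molecules (any member passing qualifies the scaffold) instead of on the
    scaffold itself.
    """
    cfg = config or FilterConfig()
    records, rejects = sanitize_library(entries)
    scaffolds = build_scaffold_records(records, keep_alpha=cfg.keep_alpha)
    if cfg.filter_level == "molecule":
        by_id = {r.id: r for r in records}
        for rec in scaffolds.values():
            if rec.smiles == "":
                continue
            members = [by_id[m] for m in rec.members]
            rec.rotatable_bonds = min(m.rotatable_bonds for m in members)
            rec.heavy_atoms = max(m.heavy_atoms for m in members)
    passing = apply_scaffold_filters(scaffolds, cfg, hts_frequency)
    passing_smiles = {s.smiles for s in passing}
    selected = [r for r in records if r.scaffold_id in passing_smiles]
    ranked = rank_by_complexity(selected)
    for rec in records:
        rec.verdicts["scaffold_filters"] = rec.scaffold_id in passing_smiles
        check_ro3(rec, cfg)
    profile = profile_library(ranked) if ranked else None
    return {
        "records": ranked,
        "rejects": rejects,
        "scaffolds": scaffolds,
        "passing_scaffolds": passing,
        "profile": profile,
    }


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Flatten compound records (with verdicts) for CSV export."""
    rows = []
    for r in records:
        row = {
            "id": r.id, "smiles": r.smiles, "mw": r.mw,
            "heavy_atoms": r.heavy_atoms, "clogp": r.clogp, "psa": r.psa,
            "hba": r.hba, "hbd": r.hbd, "rotatable_bonds": r.rotatable_bonds,
            "ring_count": r.ring_count, "scaffold": r.scaffold_id,
            "complexity": r.complexity,
        }
        row.update({f"verdict_{k}": v for k, v in r.verdicts.items()})
        rows.append(row)
    return pd.DataFrame(rows)
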