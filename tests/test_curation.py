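"""Library sanitisation, scaffolding, filter cascade, ranking and profiling."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from idpfrag.curation import (
    CompoundRecord,
    FilterConfig,
    ScaffoldRecord,
    apply_scaffold_filters,
    build_scaffold_records,
    check_ro3,
    curate_library,
    murcko_scaffold,
    oprea_complexity,
    profile_library,
    rank_by_complexity,
    sanitize_library,
)
from idpfrag.synthetic import LibrarySimSpec, default_library_spec, simulate_library


class TestSanitize:
    def test_benzene_is_valid(self):
        valid, rejects = sanitize_library([("benzene", "c1ccccc1")])
        assert [v.id for v in valid] == ["benzene"] and not rejects

    @pytest.mark.parametrize("smiles, reason", [
        ("[13CH4]", "isotope"),
        ("CC(=O)O[Fe]", "inorganic"),
        ("C1CC(", "invalid"),
        ("[SiH3]c1ccccc1", "inorganic"),
    ])
    def test_rejects_are_tagged(self, smiles, reason):
        valid, rejects = sanitize_library([("x", smiles)])
        assert not valid and rejects == [("x", reason)]

    def test_empty_input_is_not_an_error(self):
        assert sanitize_library([]) == ([], [])


class TestMurckoScaffold:
    def test_all_ring_molecule_is_its_own_scaffold(self):
        mol = Chem.MolFromSmiles("c1ccc(-c2ccccc2)cc1")
        assert murcko_scaffold(mol, keep_alpha=True) == Chem.CanonSmiles(
            "c1ccc(-c2ccccc2)cc1")

    def test_alpha_atom_is_preserved(self):
        # ethylbenzene -> benzene plus the attached alpha carbon (toluene shape)
        mol = Chem.MolFromSmiles("CCc1ccccc1")
        assert murcko_scaffold(mol, keep_alpha=True) == Chem.CanonSmiles("Cc1ccccc1")
        assert murcko_scaffold(mol, keep_alpha=False) == Chem.CanonSmiles("c1ccccc1")

    def test_acyclic_molecule_has_empty_scaffold(self):
        assert murcko_scaffold(Chem.MolFromSmiles("CCCCCC")) == ""

    def test_linker_between_rings_is_kept(self):
        mol = Chem.MolFromSmiles("c1ccccc1CCc1ccncc1")
        bare = murcko_scaffold(mol, keep_alpha=False)
        assert bare == Chem.CanonSmiles("c1ccc(CCc2ccncc2)cc1")

    @pytest.mark.parametrize("smiles", [
        "CCc1ccccc1", "CCc1ccc(C(C)=O)cc1", "O=C(O)Cc1ccc2ccccc2c1",
        "CCN(CC)c1ccnc(C)n1",
    ])
    def test_bare_scaffold_is_subgraph_of_alpha_scaffold(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        bare = Chem.MolFromSmiles(murcko_scaffold(mol, keep_alpha=False))
        alpha = Chem.MolFromSmiles(murcko_scaffold(mol, keep_alpha=True))
        assert alpha.HasSubstructMatch(bare)


def _scaffold_record(smiles="Cc1ccc2ccccc2c1", **overrides):
    mol = Chem.MolFromSmiles(smiles)
    from idpfrag.curation import _ring_substitutions
    from rdkit.Chem import Lipinski, rdMolDescriptors

    fields = dict(
        smiles=Chem.MolToSmiles(mol),
        members=["m1"],
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        ring_count=rdMolDescriptors.CalcNumRings(mol),
        ring_substitutions=_ring_substitutions(mol),
    )
    fields.update(overrides)
    return ScaffoldRecord(**fields)


class TestScaffoldFilters:
    def test_frequency_boundary_at_eight(self):
        cfg = FilterConfig()
        rec = _scaffold_record()
        freq = {rec.smiles: 8}
        assert apply_scaffold_filters([rec], cfg, freq) == [rec]
        rec7 = _scaffold_record()
        assert apply_scaffold_filters([rec7], cfg, {rec7.smiles: 7}) == []
        assert "hts_frequency" in rec7.failure_reasons

    def test_single_ring_needs_more_than_one_substitution(self):
        # toluene skeleton: one ring, one substitution -> fails
        rec = _scaffold_record("Cc1ccccc1")
        assert apply_scaffold_filters([rec], FilterConfig(), {rec.smiles: 99}) == []
        assert "ring_substitutions" in rec.failure_reasons
        # xylene skeleton: one ring, two substitutions -> substitution rule ok
        rec2 = _scaffold_record("Cc1ccccc1C")
        apply_scaffold_filters([rec2], FilterConfig(), {rec2.smiles: 99})
        assert rec2.verdicts["ring_substitutions"]

    def test_nine_heavy_atoms_fail(self):
        rec = _scaffold_record("Cc1ccccc1C")  # 8 heavy atoms
        apply_scaffold_filters([rec], FilterConfig(), {rec.smiles: 99})
        assert not rec.verdicts["heavy_atoms"]
        rec10 = _scaffold_record()  # methylnaphthalene: 11 heavy atoms
        apply_scaffold_filters([rec10], FilterConfig(), {rec10.smiles: 99})
        assert rec10.verdicts["heavy_atoms"]

    def test_reactive_substructure_fails(self):
        rec = _scaffold_record("O=CNc1ccc2ccccc2c1")  # formamide is fine
        rec_bad = _scaffold_record("ClC(=O)c1ccc2ccccc2c1")  # acyl chloride
        freq = {rec.smiles: 99, rec_bad.smiles: 99}
        passing = apply_scaffold_filters([rec, rec_bad], FilterConfig(), freq)
        assert rec in passing and rec_bad not in passing
        assert any(r.startswith("reactive") for r in rec_bad.failure_reasons)

    def test_missing_frequency_counts_as_zero(self):
        rec = _scaffold_record()
        assert apply_scaffold_filters([rec], FilterConfig(), {}) == []
        assert rec.hts_frequency == 0

    def test_output_invariant_to_input_order(self):
        recs = [_scaffold_record(), _scaffold_record("Cc1ccc2ncccc2c1")]
        freq = {r.smiles: 10 for r in recs}
        fwd = [r.smiles for r in apply_scaffold_filters(recs, FilterConfig(), freq)]
        rev = [r.smiles for r in apply_scaffold_filters(recs[::-1], FilterConfig(), freq)]
        assert fwd == rev


class TestComplexityRanking:
    def _record(self, rid, score):
        mol = Chem.MolFromSmiles("c1ccccc1")
        rec = sanitize_library([(rid, "c1ccccc1")])[0][0]
        rec.complexity = score
        return rec

    def test_descending_with_id_tiebreak(self):
        recs = [self._record("a", 3), self._record("b", 5), self._record("c", 5)]
        assert [r.id for r in rank_by_complexity(recs)] == ["b", "c", "a"]

    def test_single_record(self):
        recs = [self._record("only", 1.0)]
        assert rank_by_complexity(recs) == recs

    def test_permutation_invariant_matches_naive_sort(self, rng):
        scores = rng.integers(0, 5, size=12).astype(float)
        recs = [self._record(f"m{i}", s) for i, s in enumerate(scores)]
        expected = [r.id for r in sorted(recs, key=lambda r: (-r.complexity, r.id))]
        for _ in range(3):
            perm = [recs[i] for i in rng.permutation(len(recs))]
            assert [r.id for r in rank_by_complexity(perm)] == expected

    def test_score_increases_with_rings_and_heteroatoms(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        quinoline = Chem.MolFromSmiles("c1ccc2ncccc2c1")
        assert oprea_complexity(quinoline) > oprea_complexity(benzene)


class TestRuleOfThree:
    def _record(self, **props):
        rec = sanitize_library([("x", "c1ccccc1")])[0][0]
        for k, v in props.items():
            setattr(rec, k, v)
        return rec

    def test_boundary_values_pass(self):
        rec = self._record(mw=299.9, hbd=3, hba=3, clogp=3.0)
        passed, detail = check_ro3(rec)
        assert passed and all(v is True for v in detail.values())

    def test_mw_300_fails_strictly(self):
        passed, detail = check_ro3(self._record(mw=300.0))
        assert not passed and detail["mw"] is False

    def test_four_acceptors_fail(self):
        passed, detail = check_ro3(self._record(hba=4))
        assert not passed and detail["hba"] is False

    def test_missing_property_reports_uncomputed(self):
        passed, detail = check_ro3(self._record(clogp=float("nan")))
        assert not passed and detail["clogp"] == "uncomputed"


class TestProfile:
    def test_two_molecule_mean_and_sample_sd(self):
        recs = sanitize_library([("a", "c1ccccc1"), ("b", "c1ccncc1")])[0]
        recs[0].mw, recs[1].mw = 200.0, 300.0
        prof = profile_library(recs)
        assert prof.loc["mw", "mean"] == pytest.approx(250.0)
        assert prof.loc["mw", "sd"] == pytest.approx(70.71, abs=0.01)

    def test_benzene_descriptors(self):
        rec = sanitize_library([("benzene", "c1ccccc1")])[0][0]
        assert rec.mw == pytest.approx(78.11, abs=0.01)
        assert (rec.heavy_atoms, rec.hbd, rec.hba) == (6, 0, 0)

    def test_singleton_reports_zero_sd_with_warning(self):
        recs = sanitize_library([("a", "c1ccccc1")])[0]
        with pytest.warns(UserWarning, match="single"):
            prof = profile_library(recs)
        assert (prof["sd"] == 0).all()

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError):
            profile_library([])


class TestPipeline:
    def test_verdicts_match_simulated_ground_truth(self):
        lib = simulate_library(default_library_spec())
        result = curate_library(lib.entries, lib.hts_frequency)
        selected = {r.id for r in result["records"]}
        for mol_id, row in lib.truth.iterrows():
            if row["is_decoy"]:
                assert mol_id not in selected
            else:
                assert row["passes_frequency"] == (mol_id in selected)

    def test_decoys_rejected_with_matching_reason(self):
        spec = default_library_spec()
        lib = simulate_library(LibrarySimSpec(
            scaffolds=spec.scaffolds, substituents=spec.substituents,
            multiplicity=dict(spec.multiplicity), decoy_fraction=0.2, seed=5))
        result = curate_library(lib.entries, lib.hts_frequency)
        rejected = dict(result["rejects"])
        decoys = lib.truth[lib.truth["is_decoy"]]
        assert set(decoys.index) == set(rejected)
        for mol_id, row in decoys.iterrows():
            assert rejected[mol_id] == row["decoy_kind"]

    def test_pipeline_is_idempotent(self):
        lib = simulate_library(default_library_spec())
        first = curate_library(lib.entries, lib.hts_frequency)
        entries2 = [(r.id, r.smiles) for r in first["records"]]
        second = curate_library(entries2, lib.hts_frequency)
        assert {r.id for r in second["records"]} == {r.id for r in first["records"]}
        assert not second["rejects"]

    def test_selection_invariant_to_input_order(self):
        lib = simulate_library(default_library_spec())
        fwd = curate_library(lib.entries, lib.hts_frequency)
        rev = curate_library(lib.entries[::-1], lib.hts_frequency)
        assert ({r.id for r in fwd["records"]}
                == {r.id for r in rev["records"]})
        assert [r.id for r in fwd["records"]] == [r.id for r in rev["records"]]
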