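import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclomimic import (
    InterfaceDefinition,
    MatchParams,
    parse_pdb,
    resolve_hotspots,
    run_matching,
)
from cyclomimic.design import (
    DesignedPeptide,
    MutationEntry,
    MutationPlan,
    apply_plan_to_sequence,
    build_design,
    derive_mutation_plan,
    graft_side_chains,
    mutation_tokens,
    rank_designs,
    validate_plan,
    write_design_outputs,
)
from cyclomimic.errors import DesignError
from cyclomimic.interface import EnergyTable
from cyclomimic.peptide_db import detect_cyclization
from cyclomimic.structure import Atom3D, MolecularModel

from conftest import make_residue


def plan_from(pairs):
    """pairs: list of (1-based position, one-letter target)."""
    one_to_three = {"T": "THR", "N": "ASN", "K": "LYS", "R": "ARG"}
    return MutationPlan([
        MutationEntry(pos - 1, f"A:{aa}{100 + i}", one_to_three[aa])
        for i, (pos, aa) in enumerate(pairs)])


class TestApplyPlanToSequence:
    def test_18mer_triple_substitution(self):
        # R2T, Y3N, I7K on a disulfide-bridged 18-mer
        plan = plan_from([(2, "T"), (3, "N"), (7, "K")])
        assert apply_plan_to_sequence("GRYRRCIPGMFRAYCYMD", plan) == \
            "GTNRRCKPGMFRAYCYMD"

    def test_13mer_quadruple_substitution(self):
        plan = plan_from([(2, "N"), (3, "R"), (4, "R"), (7, "K")])
        assert apply_plan_to_sequence("CQLINTNGSWHIC", plan) == \
            "CNRRNTKGSWHIC"

    def test_empty_plan_is_identity(self):
        assert apply_plan_to_sequence("GRYRR", MutationPlan([])) == "GRYRR"

    def test_out_of_range_position_is_error(self):
        with pytest.raises(DesignError):
            apply_plan_to_sequence("GR", plan_from([(7, "K")]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=1000))
    def test_idempotent_and_length_preserving(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
        positions = rng.choice(12, size=3, replace=False)
        plan = MutationPlan([MutationEntry(int(p), f"A:K{p}", "LYS")
                             for p in positions])
        once = apply_plan_to_sequence(seq, plan)
        assert len(once) == len(seq)
        assert apply_plan_to_sequence(once, plan) == once

    def test_mutation_token_rendering(self):
        plan = plan_from([(3, "N")])
        assert mutation_tokens(plan, "GRYRR") == ["Y3N"]


@pytest.fixture
def passed_match(planted_setup):
    model, record, db, motif, planted = planted_setup
    iface = InterfaceDefinition(
        "A", resolve_hotspots(planted.model, planted.hotspot_labels),
        ligand_chain="L")
    result = run_matching(planted.model, iface, db, MatchParams(motif_size=5))
    return model, record, db, motif, planted, result.passed[0]


class TestDeriveMutationPlan:
    def test_one_entry_per_matched_position(self, passed_match):
        model, record, db, motif, planted, match = passed_match
        plan = derive_mutation_plan(match, model.chain("P"))
        assert len(plan.entries) == 5
        assert [e.peptide_index for e in plan.entries] == list(motif)
        assert [e.target_label for e in plan.entries] == planted.hotspot_labels

    def test_identical_residues_flagged_no_op(self, passed_match):
        model, record, db, motif, planted, match = passed_match
        plan = derive_mutation_plan(match, model.chain("P"))
        # planted target copies the peptide's own residue types
        assert all(e.no_op for e in plan.entries)

    def test_unpassed_match_is_error(self, passed_match):
        model, *_, match = passed_match
        match.status = "rejected_clash"
        with pytest.raises(DesignError):
            derive_mutation_plan(match, model.chain("P"))


ARG_SIDECHAIN = [("CB", "C", (1.0, 1.2, 0.3)), ("CG", "C", (2.1, 2.0, 0.6)),
                 ("CD", "C", (3.3, 1.6, 1.1)), ("NE", "N", (4.4, 2.5, 1.3)),
                 ("CZ", "C", (5.6, 2.2, 1.8)), ("NH1", "N", (5.9, 1.0, 2.2)),
                 ("NH2", "N", (6.6, 3.1, 1.9))]
BACKBONE = [("N", "N", (-1.2, 0.5, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, -0.4)), ("O", "O", (1.4, 1.9, -0.5))]


def graft_fixture(offset=(10.0, 0.0, 0.0)):
    """GLY peptide residue and an ARG target residue, backbone-shifted."""
    target = make_residue("A", 101, "ARG", BACKBONE + ARG_SIDECHAIN)
    shifted = [(n, e, tuple(np.add(p, offset))) for n, e, p in BACKBONE]
    pep = make_residue("P", 3, "GLY", shifted)
    model = MolecularModel([("P", [pep])])
    plan = MutationPlan([MutationEntry(0, "A:R101", "ARG",
                                      target_residue=target)])
    return model, plan, target


class TestGraftSideChains:
    def test_gly_gains_arg_side_chain_backbone_untouched(self):
        model, plan, target = graft_fixture()
        before = np.array([a.position for a in model.chain("P")[0].atoms])
        out = graft_side_chains(model, plan, "P")
        res = out.chain("P")[0]
        assert res.res_name == "ARG"
        names = [a.name for a in res.atoms]
        assert names[:4] == ["N", "CA", "C", "O"]
        assert set(names[4:]) == {n for n, _, _ in ARG_SIDECHAIN}
        after = np.array([res.atom(n).position for n in ("N", "CA", "C", "O")])
        np.testing.assert_array_equal(after, before)  # exactly zero movement

    def test_heavy_atom_count_matches_target(self):
        model, plan, target = graft_fixture()
        out = graft_side_chains(model, plan, "P")
        assert len(out.chain("P")[0].heavy_atoms()) == len(target.heavy_atoms())

    def test_graft_onto_backbone_copy_reproduces_target(self):
        # zero offset: frames coincide, so side chain lands exactly on target
        model, plan, target = graft_fixture(offset=(0.0, 0.0, 0.0))
        out = graft_side_chains(model, plan, "P")
        res = out.chain("P")[0]
        for name, _, pos in ARG_SIDECHAIN:
            np.testing.assert_allclose(res.atom(name).position, pos, atol=1e-6)

    def test_graft_to_gly_removes_side_chain(self):
        target = make_residue("A", 101, "GLY", BACKBONE)
        pep = make_residue("P", 1, "ARG", BACKBONE + ARG_SIDECHAIN)
        model = MolecularModel([("P", [pep])])
        plan = MutationPlan([MutationEntry(0, "A:G101", "GLY",
                                           target_residue=target)])
        out = graft_side_chains(model, plan, "P")
        assert [a.name for a in out.chain("P")[0].atoms] == ["N", "CA", "C", "O"]


class TestCyclizationProtection:
    def test_mutating_disulfide_cysteine_rejected(self, disulfide18):
        model, record = disulfide18
        chain = model.chain("P")
        cys_idx = record.sequence.index("C")
        plan = MutationPlan([MutationEntry(cys_idx, "A:K101", "LYS")])
        with pytest.raises(DesignError, match="cyclization-critical"):
            validate_plan(plan, chain, detect_cyclization(chain))

    def test_override_allows_it(self, disulfide18):
        model, record = disulfide18
        chain = model.chain("P")
        cys_idx = record.sequence.index("C")
        plan = MutationPlan([MutationEntry(cys_idx, "A:K101", "LYS")])
        validate_plan(plan, chain, detect_cyclization(chain),
                      allow_cycle_breaking=True)

    def test_head_to_tail_termini_protected(self, ring13):
        model, _ = ring13
        chain = model.chain("P")
        plan = MutationPlan([MutationEntry(0, "A:K101", "LYS")])
        with pytest.raises(DesignError):
            validate_plan(plan, chain, detect_cyclization(chain))


def toy_design(design_id, labels, fit_rmsd, match):
    plan = MutationPlan([MutationEntry(i, lab, "LYS")
                         for i, lab in enumerate(labels)])
    m = type(match)(**{**match.__dict__})
    m.fit_rmsd = fit_rmsd
    return DesignedPeptide(design_id, "pep", "P", "KKKK", "AAAA",
                           MolecularModel(), plan, m)


class TestRankDesigns:
    def test_most_negative_sum_first(self, passed_match):
        *_, match = passed_match
        table = EnergyTable({"A:K1": -10.0, "A:K2": -20.0, "A:K3": -10.0})
        d1 = toy_design("d1", ["A:K1", "A:K3"], 1.0, match)   # -20
        d2 = toy_design("d2", ["A:K2", "A:K3"], 1.0, match)   # -30
        ranked = rank_designs([d1, d2], table)
        assert [d.design_id for d in ranked] == ["d2", "d1"]
        assert ranked[0].rank_score == pytest.approx(-30.0)

    def test_tie_broken_by_fit_rmsd(self, passed_match):
        *_, match = passed_match
        table = EnergyTable({"A:K1": -10.0})
        d1 = toy_design("d1", ["A:K1"], 2.4, match)
        d2 = toy_design("d2", ["A:K1"], 1.2, match)
        assert [d.design_id for d in rank_designs([d1, d2], table)] == \
            ["d2", "d1"]

    def test_empty_table_scores_zero_order_by_rmsd(self, passed_match):
        *_, match = passed_match
        d1 = toy_design("d1", ["A:K1"], 2.4, match)
        d2 = toy_design("d2", ["A:K2"], 1.2, match)
        ranked = rank_designs([d1, d2], EnergyTable({}))
        assert all(d.rank_score == 0.0 for d in ranked)
        assert [d.design_id for d in ranked] == ["d2", "d1"]

    def test_output_is_permutation_with_recomputable_scores(self, passed_match):
        *_, match = passed_match
        table = EnergyTable({f"A:K{i}": -float(i) for i in range(1, 6)})
        designs = [toy_design(f"d{i}", [f"A:K{i}", f"A:K{i % 5 + 1}"], 1.0, match)
                   for i in range(1, 5)]
        ranked = rank_designs(designs, table)
        assert sorted(d.design_id for d in ranked) == \
            sorted(d.design_id for d in designs)
        for d in ranked:
            expected = sum(table.get(e.target_label) for e in d.plan.entries)
            assert d.rank_score == pytest.approx(expected)


class TestDesignOutputs:
    def test_end_to_end_design_files(self, passed_match, tmp_path):
        model, record, db, motif, planted, match = passed_match
        design = build_design(match, db, allow_cycle_breaking=True)
        ranked = rank_designs([design], planted.energy_table)
        files = write_design_outputs(ranked, tmp_path)
        pdbs = [f for f in files if f.suffix == ".pdb"]
        assert len(pdbs) == 1
        reparsed = parse_pdb(pdbs[0].read_text())
        assert reparsed.n_atoms == design.model.n_atoms
        summary = (tmp_path / "designs.tsv").read_text().splitlines()
        assert len(summary) == 2
        assert record.pdb_id in summary[1]

    def test_design_score_sums_planted_energies(self, passed_match):
        model, record, db, motif, planted, match = passed_match
        design = build_design(match, db, allow_cycle_breaking=True)
        (ranked,) = rank_designs([design], planted.energy_table)
        expected = sum(planted.energy_table.get(lab)
                       for lab in planted.hotspot_labels)
        assert ranked.rank_score == pytest.approx(expected)

    def test_backbone_identical_to_posed_template(self, passed_match):
        model, record, db, motif, planted, match = passed_match
        design = build_design(match, db, allow_cycle_breaking=True)
        posed = db.model_for(record).transformed(
            match.transform.rotation, match.transform.translation)
        for r_out, r_in in zip(design.model.chain("P"), posed.chain("P")):
            for name in ("N", "CA", "C"):
                np.testing.assert_array_equal(r_out.atom(name).position,
                                              r_in.atom(name).position)
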