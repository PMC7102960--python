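"""Topology analysis: torsions, tetrads, polarity, loops, locks, RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from quadlock import synthetic_data as sd
from quadlock.geometry import dihedral_deg, place_atom
from quadlock.structure_topology import (Residue, StackingError,
                                         StructureModel, analyze_model,
                                         analyze_topology, assemble_tetrads,
                                         classify_chi, compute_chi,
                                         detect_hoogsteen_edges,
                                         ensemble_rmsd,
                                         order_stack_and_polarity)

RNG = np.random.default_rng(42)


def _ideal_guanine_with_chi(chi_deg: float) -> Residue:
    atoms = {k: v.copy() for k, v in sd.GUANINE_FRAME.items()}
    atoms["O4'"] = place_atom(atoms["C4"], atoms["N9"], atoms["C1'"],
                              1.42, 108.0, chi_deg)
    return Residue("A", 1, "DG", atoms)


def _transform(res: Residue, rot=None, shift=None) -> Residue:
    rot = np.eye(3) if rot is None else rot
    shift = np.zeros(3) if shift is None else shift
    return Residue(res.chain, res.number, res.name,
                   {k: rot @ v + shift for k, v in res.atoms.items()})


class TestChi:
    @pytest.mark.parametrize("chi", [10.0, 60.0, 210.0, 300.0, 317.0])
    def test_constructed_torsion_is_recovered(self, chi):
        assert compute_chi(_ideal_guanine_with_chi(chi)) == pytest.approx(
            chi, abs=1e-6
        )

    def test_rotation_translation_invariance(self):
        res = _ideal_guanine_with_chi(210.0)
        for _ in range(10):
            rot = Rotation.random(random_state=RNG).as_matrix()
            moved = _transform(res, rot, RNG.uniform(-50, 50, 3))
            assert compute_chi(moved) == pytest.approx(210.0, abs=1e-6)

    def test_mirror_antisymmetry(self):
        res = _ideal_guanine_with_chi(210.0)
        mirrored = _transform(res, np.diag([1.0, 1.0, -1.0]))
        assert compute_chi(mirrored) == pytest.approx(150.0, abs=1e-6)

    def test_missing_atom_error_names_residue_and_atom(self):
        res = _ideal_guanine_with_chi(210.0)
        del res.atoms["O4'"]
        with pytest.raises(KeyError, match="O4'"):
            compute_chi(res)

    def test_place_atom_agrees_with_dihedral(self):
        a, b, c = np.array([0.0, 0, 0]), np.array([1.5, 0, 0]), \
            np.array([2.0, 1.4, 0])
        d = place_atom(a, b, c, 1.4, 109.0, 123.4)
        assert dihedral_deg(a, b, c, d) == pytest.approx(123.4, abs=1e-8)


class TestClassifyChi:
    @pytest.mark.parametrize(
        "chi, klass",
        [(75.2, "syn"), (319.4, "undefined"), (155.4, "undefined"),
         (210.0, "anti"), (317.0, "undefined"),
         (0.0, "undefined"), (90.0, "undefined"), (180.0, "undefined"),
         (240.0, "undefined")],
    )
    def test_ranges_with_open_boundaries(self, chi, klass):
        assert classify_chi(chi) == klass

    def test_total_function_over_fine_grid(self):
        seen = set()
        for chi in np.arange(0.0, 360.0, 0.1):
            k = classify_chi(float(chi))
            assert k in ("syn", "anti", "undefined")
            seen.add(k)
        assert seen == {"syn", "anti", "undefined"}


class TestHoogsteenAndTetrads:
    def test_single_tetrad_gives_one_4cycle(self):
        models, _ = sd.build_ideal_g4(sd.fixture_single_tetrad())
        edges = detect_hoogsteen_edges(models[0])
        assert len(edges) == 4
        tets = assemble_tetrads(edges)
        assert len(tets) == 1
        assert set(tets[0].composition()) == {"G1", "G2", "G3", "G4"}
        assert tets[0].planarity_rmsd < 0.1

    def test_distant_guanines_make_no_edge(self):
        g1 = _ideal_guanine_with_chi(210.0)
        g2 = _transform(_ideal_guanine_with_chi(210.0),
                        shift=np.array([20.0, 0, 0]))
        g2.number = 2
        model = StructureModel(1, [g1, g2])
        assert detect_hoogsteen_edges(model) == []

    def test_open_chain_is_not_a_tetrad(self):
        models, _ = sd.build_ideal_g4(sd.fixture_single_tetrad())
        edges = detect_hoogsteen_edges(models[0])[:3]
        assert assemble_tetrads(edges) == []

    def test_intra_locked_fixture_recovers_planted_compositions(
        self, at26_fixture
    ):
        model, truth = at26_fixture
        tets = assemble_tetrads(detect_hoogsteen_edges(model))
        got = sorted(sorted(t.composition()) for t in tets)
        assert got == sorted(truth["tetrads"])


class TestStackAndPolarity:
    def test_parallel_stack_all_same(self, parallel3_fixture):
        model, _ = parallel3_fixture
        stack = order_stack_and_polarity(
            assemble_tetrads(detect_hoogsteen_edges(model))
        )
        assert stack.relative_polarity == ["same", "same"]

    def test_inner_layer_reversal(self, at26_fixture):
        model, truth = at26_fixture
        stack = order_stack_and_polarity(
            assemble_tetrads(detect_hoogsteen_edges(model))
        )
        assert stack.relative_polarity == truth["relative_polarity"]
        assert stack.relative_polarity[1] == "reverse"

    def test_mirror_flips_signs_but_not_relative_polarity(
        self, parallel3_fixture
    ):
        model, _ = parallel3_fixture
        stack = order_stack_and_polarity(
            assemble_tetrads(detect_hoogsteen_edges(model))
        )
        # reflect through a plane containing the stacking axis, so the
        # cycle circulation flips while the layer order is preserved
        mirrored = StructureModel(
            2, [_transform(r, np.diag([1.0, -1.0, 1.0]))
                for r in model.residues]
        )
        mstack = order_stack_and_polarity(
            assemble_tetrads(detect_hoogsteen_edges(mirrored))
        )
        assert mstack.relative_polarity == stack.relative_polarity
        assert (
            [-s for s in mstack.polarity_signs] == stack.polarity_signs
            or [-s for s in reversed(mstack.polarity_signs)]
            == stack.polarity_signs
        )

    def test_two_separated_stacks_raise_with_blocks(self):
        models, _ = sd.build_ideal_g4(sd.fixture_single_tetrad())
        far, _ = sd.build_ideal_g4(sd.fixture_single_tetrad())
        shifted = [
            _transform(r, shift=np.array([0.0, 0.0, 30.0]))
            for r in far[0].residues
        ]
        for r in shifted:
            r.number += 10
        both = StructureModel(1, models[0].residues + shifted)
        tets = assemble_tetrads(detect_hoogsteen_edges(both))
        assert len(tets) == 2
        with pytest.raises(StackingError) as err:
            order_stack_and_polarity(tets)
        assert len(err.value.blocks) == 2

    def test_single_tetrad_cannot_stack(self):
        models, _ = sd.build_ideal_g4(sd.fixture_single_tetrad())
        tets = assemble_tetrads(detect_hoogsteen_edges(models[0]))
        with pytest.raises(ValueError):
            order_stack_and_polarity(tets)


class TestLoopsAndLock:
    def test_full_loop_taxonomy_on_intra_locked_fixture(self, at26_fixture):
        model, _ = at26_fixture
        topo = analyze_model(model)
        got = {
            (lp.flank5.label(), lp.flank3.label()): (lp.kind, lp.span_layers)
            for lp in topo.loops
        }
        assert got == {
            ("G2", "G3"): ("V_R", 3),
            ("G3", "G5"): ("bulge", 2),
            ("G6", "G8"): ("propeller", 2),
            ("G9", "G11"): ("propeller", 2),
            ("G12", "G15"): ("V_S", 2),
            ("G15", "G17"): ("bulge", 2),
            ("G18", "G20"): ("propeller", 2),
            ("G21", "G23"): ("propeller", 2),
            ("G24", "G27"): ("edgewise", 1),
        }

    def test_three_exterior_connectors_are_propellers(
        self, parallel3_fixture
    ):
        model, _ = parallel3_fixture
        topo = analyze_model(model)
        assert [lp.kind for lp in topo.loops] == ["propeller"] * 3
        assert all(lp.span_layers == 3 for lp in topo.loops)

    def test_unsupported_column_connector_is_vs(self):
        models, _ = sd.build_ideal_g4(sd.fixture_bilayer_vs())
        topo = analyze_model(models[0])
        kinds = sorted(lp.kind for lp in topo.loops)
        assert kinds == ["V_S", "propeller", "propeller", "propeller"]
        vs = next(lp for lp in topo.loops if lp.kind == "V_S")
        assert vs.span_layers == 2

    def test_intra_lock_requires_two_bridges(self, at26_fixture):
        model, _ = at26_fixture
        topo = analyze_model(model)
        assert topo.blocks == [[0, 1], [2, 3]]
        assert len(topo.bridging_linkers) == 3
        assert topo.intra_locked

    def test_single_linker_two_block_is_not_locked(self):
        models, _ = sd.build_ideal_g4(sd.fixture_two_block_single_linker())
        topo = analyze_model(models[0])
        assert len(topo.blocks) == 2
        assert len(topo.bridging_linkers) == 1
        assert not topo.intra_locked

    def test_single_block_parallel_is_not_locked(self, parallel3_fixture):
        model, _ = parallel3_fixture
        topo = analyze_model(model)
        assert topo.blocks == [[0, 1, 2]]
        assert not topo.intra_locked


class TestEnsembleRmsd:
    def test_identical_models_have_zero_rmsd(self, at26_fixture):
        model, _ = at26_fixture
        twin = StructureModel(2, [_transform(r) for r in model.residues])
        mean, sd_ = ensemble_rmsd([model, twin], "all_heavy")
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sd_ == 0.0

    def test_rigid_transform_gives_zero_after_superposition(
        self, at26_fixture
    ):
        model, _ = at26_fixture
        rot = Rotation.random(random_state=RNG).as_matrix()
        moved = StructureModel(
            2,
            [_transform(r, rot, np.array([3.0, -7.0, 12.0]))
             for r in model.residues],
        )
        mean, _ = ensemble_rmsd([model, moved], "tetrad_core_heavy")
        assert mean == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_model_order_and_common_transform(self):
        models, _ = sd.build_ideal_g4(
            sd.fixture_parallel(2), n_models=3, jitter_sd=0.1, seed=5
        )
        m1 = ensemble_rmsd(models, "all_heavy")
        m2 = ensemble_rmsd(models[::-1], "all_heavy")
        assert m1 == pytest.approx(m2)
        rot = Rotation.random(random_state=RNG).as_matrix()
        moved = [
            StructureModel(m.index,
                           [_transform(r, rot) for r in m.residues])
            for m in models
        ]
        assert ensemble_rmsd(moved, "all_heavy") == pytest.approx(m1)

    def test_inventory_mismatch_raises(self, at26_fixture):
        model, _ = at26_fixture
        broken = StructureModel(2, [_transform(r) for r in model.residues])
        del broken.residues[1].atoms["O6"]
        with pytest.raises(ValueError, match="inventory"):
            ensemble_rmsd([model, broken], "all_heavy")


class TestEnsembleConsensus:
    def test_consensus_over_jittered_ensemble(self, at26_ensemble):
        models, truth = at26_ensemble
        result = analyze_topology(models)
        cons = result["consensus"]
        assert sorted(list(t) for t in cons["tetrads"]) == sorted(
            truth["tetrads"]
        )
        assert cons["intra_locked"]
        chi = cons["chi"]
        syn = {lbl for lbl, row in chi.items() if row["class"] == "syn"}
        assert syn == {"G2", "G15", "G27"}
        assert chi["G3"]["class"] == "undefined"
        assert chi["G3"]["mean_deg"] == pytest.approx(317.0, abs=3.0)
        core_mean, _ = result["rmsd"]["tetrad_core_heavy"]
        assert 0.0 < core_mean < 0.5
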