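"""Generators: determinism, planted truth, and generator/analyzer closure."""

import numpy as np
import pytest

from quadlock import synthetic_data as sd
from quadlock.sequence_motifs import enumerate_queries, scan_sequence
from quadlock.structure_topology import (analyze_model, assemble_tetrads,
                                         detect_hoogsteen_edges)

MOTIF_8G2 = "GGTGGTGGTGGTGGTGGTGGTGG"


class TestPlantedFasta:
    def test_truth_matches_scanner_with_full_recall(self, tmp_path):
        spec = sd.PlantSpec(MOTIF_8G2, count=25, min_gap=10, seed=7,
                            query_label="8G2")
        fasta = tmp_path / "x.fa"
        bed = tmp_path / "x.bed"
        records, truth = sd.plant_motifs_fasta(
            1, 100_000, spec, fasta_path=fasta, bed_path=bed
        )
        assert len(truth) == 25
        qs = enumerate_queries(8, 0, 1, 2)
        hits = scan_sequence(records[0][1], qs,
                             sequence_id=records[0][0])
        got = {(h.sequence_id, h.start, h.end) for h in hits}
        want = {(r, s, e) for r, s, e, _ in truth}
        assert got == want  # 100% recall, zero false positives

    def test_zero_count_background_has_no_hits(self):
        spec = sd.PlantSpec(MOTIF_8G2, count=0, seed=1)
        records, truth = sd.plant_motifs_fasta(1, 5000, spec)
        assert truth == []
        assert "G" not in records[0][1]

    def test_seed_changes_coordinates_not_counts(self):
        a = sd.plant_motifs_fasta(
            1, 20_000, sd.PlantSpec(MOTIF_8G2, 5, seed=1))[1]
        b = sd.plant_motifs_fasta(
            1, 20_000, sd.PlantSpec(MOTIF_8G2, 5, seed=2))[1]
        assert len(a) == len(b) == 5
        assert a != b

    def test_bit_reproducible(self):
        r1, t1 = sd.plant_motifs_fasta(
            2, 10_000, sd.PlantSpec(MOTIF_8G2, 3, seed=9))
        r2, t2 = sd.plant_motifs_fasta(
            2, 10_000, sd.PlantSpec(MOTIF_8G2, 3, seed=9))
        assert r1 == r2 and t1 == t2

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            sd.plant_motifs_fasta(
                1, 100, sd.PlantSpec(MOTIF_8G2, 10, min_gap=10, seed=0)
            )


class TestIdealG4:
    def test_generator_analyzer_closed_loop(self, at26_fixture):
        model, truth = at26_fixture
        tets = assemble_tetrads(detect_hoogsteen_edges(model))
        assert sorted(sorted(t.composition()) for t in tets) == sorted(
            truth["tetrads"]
        )

    def test_hbond_distances_near_target(self):
        models, _ = sd.build_ideal_g4(sd.fixture_single_tetrad())
        for e in detect_hoogsteen_edges(models[0]):
            assert e.d_N2_N7 == pytest.approx(2.9, abs=0.1)
            assert e.d_N1_O6 == pytest.approx(2.9, abs=0.1)

    def test_one_layer_plan_has_one_tetrad_no_loops(self):
        models, truth = sd.build_ideal_g4(sd.fixture_single_tetrad())
        tets = assemble_tetrads(detect_hoogsteen_edges(models[0]))
        assert len(tets) == 1
        assert truth["loops"] == []

    def test_unrealizable_plans_rejected(self):
        with pytest.raises(ValueError, match="slot"):
            sd.FixtureTopology(
                1, (1,), (("G", 0, 0), ("G", 0, 0), ("G", 0, 1),
                          ("G", 0, 2)),
            )
        with pytest.raises(ValueError):
            sd.FixtureTopology(2, (1,), (("G", 0, 0),))

    def test_clash_detection(self):
        # a second copy of the same layer in the same place must clash
        plan = sd.fixture_single_tetrad()
        models, _ = sd.build_ideal_g4(plan)
        from quadlock.synthetic_data import _check_clashes
        from quadlock.structure_topology import Residue

        res = models[0].residues
        shifted = [
            Residue(r.chain, r.number + 10, r.name,
                    {k: v + 0.3 for k, v in r.atoms.items()})
            for r in res
        ]
        with pytest.raises(ValueError, match="clash"):
            _check_clashes(res + shifted)

    def test_models_reproducible_and_distinct(self):
        m1, _ = sd.build_ideal_g4(sd.fixture_parallel(2), n_models=3,
                                  jitter_sd=0.1, seed=4)
        m2, _ = sd.build_ideal_g4(sd.fixture_parallel(2), n_models=3,
                                  jitter_sd=0.1, seed=4)
        for a, b in zip(m1, m2):
            for ra, rb in zip(a.residues, b.residues):
                for k in ra.atoms:
                    assert np.allclose(ra.atoms[k], rb.atoms[k])
        a0 = m1[0].residues[0].atoms["N9"]
        a1 = m1[1].residues[0].atoms["N9"]
        assert not np.allclose(a0, a1)

    def test_planned_chi_realized(self, at26_fixture):
        from quadlock.structure_topology import classify_chi, compute_chi

        model, truth = at26_fixture
        for g in model.guanines:
            klass = truth["chi"][g.label()]
            assert classify_chi(compute_chi(g)) == klass


class TestSimulatedMelting:
    def test_theta_is_half_at_tm_by_construction(self):
        c = sd.simulate_melting_curve(40.8, -45.0, step=0.1)
        i = int(np.argmin(np.abs(c.temperature - 40.8)))
        # signal = theta with unit flat baselines
        assert c.signal[i] == pytest.approx(0.5, abs=1e-3)

    def test_deterministic_per_seed(self):
        a = sd.simulate_melting_curve(40.0, -45.0, noise_sd=0.01, seed=3)
        b = sd.simulate_melting_curve(40.0, -45.0, noise_sd=0.01, seed=3)
        assert np.allclose(a.signal, b.signal)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_melting_curve(5.0, -45.0)
        with pytest.raises(ValueError):
            sd.simulate_melting_curve(40.0, +45.0)
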