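"""Geometry of the idealized quadruplex structure builders."""

import itertools

import numpy as np
import pytest

from g4shape.qmodel_builder import (GeometryError, build_beads_on_string,
                                    build_duplex_quadruplex_hybrid,
                                    build_hairpin_duplex, build_htert_model,
                                    build_parallel_unit, read_pdb,
                                    stack_units, write_pdb)


class TestParallelUnit:
    def test_quartet_counts_and_topology(self, parallel_unit):
        layers = parallel_unit.quartet_layers()
        assert len(layers) == 3
        assert all(len(l["residues"]) == 4 for l in layers)
        n_quartet = sum(r.role == "quartet" for r in parallel_unit.residues)
        n_loop = sum(r.role == "loop" for r in parallel_unit.residues)
        assert n_quartet == 12 and n_loop == 4  # 1XAV-like (1,2,1) loops

    def test_rise_readback(self, parallel_unit):
        z = [l["z"] for l in parallel_unit.quartet_layers()]
        for a, b in zip(z, z[1:]):
            assert b - a == pytest.approx(3.3, abs=0.1)

    def test_quartet_planarity(self, parallel_unit):
        assert all(l["rms_out_of_plane"] < 0.5
                   for l in parallel_unit.quartet_layers())

    def test_clash_free(self, parallel_unit):
        assert parallel_unit.check_clashes() == []

    def test_c1_diagonal_near_15A(self, parallel_unit):
        bottom = parallel_unit.quartet_layers()[0]["residues"]
        c1 = [r.coords[r.atom_names.index("C1'")] for r in bottom]
        diag = max(np.linalg.norm(a - b)
                   for a, b in itertools.combinations(c1, 2))
        assert diag == pytest.approx(15.0, abs=1.5)

    def test_single_quartet_rejected(self):
        with pytest.raises(GeometryError):
            build_parallel_unit(1, (1, 2, 1))

    def test_zero_length_loop_rejected(self):
        with pytest.raises(GeometryError):
            build_parallel_unit(3, (1, 0, 1))

    def test_determinism(self):
        a = build_parallel_unit(3, (2, 3, 2))
        b = build_parallel_unit(3, (2, 3, 2))
        assert np.array_equal(a.coords(), b.coords())


class TestStacking:
    def test_nine_layers_on_one_axis(self):
        units = [build_parallel_unit(3, (1, 2, 1), unit_index=i,
                                     validate=False) for i in range(3)]
        stacked = stack_units(units)
        layers = stacked.quartet_layers()
        assert len(layers) == 9
        # all layers share the z axis
        for lay in layers:
            center = np.mean([r.coords[:11].mean(axis=0)
                              for r in lay["residues"]], axis=0)
            assert np.hypot(center[0], center[1]) < 1.0

    def test_axial_extent_arithmetic(self):
        units = [build_parallel_unit(3, (1, 2, 1), unit_index=i,
                                     validate=False) for i in range(3)]
        stacked = stack_units(units, interface_gap=3.4)
        z = [l["z"] for l in stacked.quartet_layers()]
        assert z[-1] - z[0] == pytest.approx(6 * 3.3 + 2 * 3.4, abs=0.5)

    def test_single_unit_identity(self, parallel_unit):
        out = stack_units([parallel_unit])
        assert np.allclose(out.coords(), parallel_unit.coords())


class TestBeadsOnString:
    def test_no_interquartet_stacking(self):
        units = [build_parallel_unit(3, (1, 2, 1), unit_index=i,
                                     validate=False) for i in range(3)]
        beads = build_beads_on_string(units, linker_nt=3)
        z = sorted(l["z"] for l in beads.quartet_layers())
        gaps = np.diff(z)
        # two inter-unit plane separations of linker_nt * 5.9 A
        assert sorted(gaps)[-2] > 10.0

    def test_more_extended_than_stack(self):
        mk = lambda: [build_parallel_unit(3, (1, 2, 1), unit_index=i,
                                          validate=False) for i in range(3)]
        stacked = stack_units(mk())
        beads = build_beads_on_string(mk(), linker_nt=3)
        assert beads.radius_of_gyration() > stacked.radius_of_gyration()

    def test_single_unit_identity(self, parallel_unit):
        out = build_beads_on_string([parallel_unit])
        assert np.allclose(out.coords(), parallel_unit.coords())


class TestHairpinAndHybrid:
    def test_duplex_step_count_and_diameter(self):
        hp = build_hairpin_duplex(8, 4)
        duplex = [r for r in hp.residues if r.role == "duplex"]
        assert len(duplex) == 16  # 8 paired steps
        xyz = np.vstack([r.coords for r in duplex])
        radial = np.hypot(xyz[:, 0], xyz[:, 1])
        assert 2 * radial.max() == pytest.approx(20.0, abs=3.0)

    def test_zero_bp_hairpin_rejected(self):
        with pytest.raises(GeometryError):
            build_duplex_quadruplex_hybrid(hairpin_bp=0)

    def test_hybrid_composition(self):
        hyb = build_htert_model("hybrid")
        roles = {r.role for r in hyb.residues}
        assert {"quartet", "duplex", "linker"} <= roles
        assert sum(r.role == "quartet" for r in hyb.residues) == 24


class TestHtertModels:
    @pytest.mark.parametrize("kind", ["stacked", "beads", "hybrid"])
    def test_full_sequence_complement_and_validity(self, kind):
        m = build_htert_model(kind)
        assert len(m.residues) == 68
        assert m.check_clashes() == []
        assert m.provenance["mass_da"] == pytest.approx(21632.8, abs=0.2)

    def test_compactness_ordering(self):
        rg = {k: build_htert_model(k).radius_of_gyration()
              for k in ("stacked", "beads")}
        assert rg["stacked"] < rg["beads"]


def test_pdb_round_trip(tmp_path, parallel_unit):
    path = tmp_path / "unit.pdb"
    write_pdb(parallel_unit, path)
    back = read_pdb(path)
    assert back.n_atoms == parallel_unit.n_atoms
    assert np.allclose(back.coords(), parallel_unit.coords(), atol=1e-3)
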