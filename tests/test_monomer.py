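"""Monomer construction, pair interactions, variants, and the dimerization
free-energy calibration handle."""

import numpy as np
import pytest

from fiberex.monomer import (
    BEAD_CLASSES,
    MonomerSpec,
    dimerization_free_energy,
    eps_lookup,
    make_monomer,
    pair_energy,
    variant_monomer,
)


def _polygon_area(pts2d):
    x, y = pts2d[:, 0], pts2d[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


class TestMakeMonomer:
    @pytest.mark.parametrize(
        "shape,arms,n_core,n_arm",
        [("triangle3", 3, 3, 12), ("square4", 4, 4, 16)],
    )
    def test_structural_bead_counts(self, shape, arms, n_core, n_arm):
        topo = make_monomer(MonomerSpec(core_shape=shape, arm_count=arms))
        # core + dipole-bearing center + arms; the two charge sites live
        # inside the center bead and are not structural beads
        structural = topo.n_beads - 2
        assert structural == n_core + 1 + n_arm
        assert len(topo.core_indices) == n_core
        assert len(topo.arm_indices) == n_arm

    def test_core_area_scaling_exact(self):
        base = make_monomer(MonomerSpec(core_area_scale=1.0))
        big = make_monomer(MonomerSpec(core_area_scale=1.5))
        a0 = _polygon_area(base.positions[base.core_indices][:, :2])
        a1 = _polygon_area(big.positions[big.core_indices][:, :2])
        assert a1 == pytest.approx(1.5 * a0, rel=1e-12)

    def test_square4_matches_triangle_area(self):
        tri = make_monomer(MonomerSpec(core_shape="triangle3"))
        sq = make_monomer(MonomerSpec(core_shape="square4", arm_count=4))
        assert _polygon_area(sq.positions[sq.core_indices][:, :2]) == pytest.approx(
            _polygon_area(tri.positions[tri.core_indices][:, :2]), rel=1e-12
        )

    def test_unknown_core_shape_rejected_naming_enum(self):
        with pytest.raises(ValueError, match="triangle3"):
            MonomerSpec(core_shape="hexagon")

    def test_dipole_sites_symmetric_and_charged(self):
        spec = MonomerSpec()
        topo = make_monomer(spec)
        plus, minus = topo.dipole_indices
        assert topo.charges[plus] == pytest.approx(spec.dipole_charge)
        assert topo.charges[minus] == pytest.approx(-spec.dipole_charge)
        sep = np.linalg.norm(topo.positions[plus] - topo.positions[minus])
        assert sep == pytest.approx(spec.dipole_separation)

    def test_core_beads_coplanar_and_bond_graph_connected(self):
        topo = make_monomer(MonomerSpec(core_shape="square9", arm_count=4))
        assert np.allclose(topo.positions[topo.core_indices][:, 2], 0.0)
        # BFS over bonds reaches every bead
        adj = {i: set() for i in range(topo.n_beads)}
        for i, j, _ in topo.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        assert len(seen) == topo.n_beads

    def test_inner_outer_arm_classes(self):
        topo = make_monomer(variant_monomer(3))
        arm_classes = [topo.classes[i] for i in topo.arm_indices]
        # per arm: inner two solvophobic, outer two solvophilic
        for a in range(0, len(arm_classes), 4):
            assert arm_classes[a : a + 2] == ["N0", "N0"]
            assert arm_classes[a + 2 : a + 4] == ["C1", "C1"]


class TestVariants:
    def test_variant1_completely_solvophilic(self):
        spec = variant_monomer(1)
        assert spec.inner_arm_class == spec.outer_arm_class == "C1"

    def test_variant3_strong_tier_same_charge(self):
        spec = variant_monomer(3)
        assert BEAD_CLASSES[spec.inner_arm_class].solvophobicity_tier == 2
        assert spec.dipole_charge == pytest.approx(1.45)

    def test_variants_differ_only_in_inner_class(self):
        s2, s3 = variant_monomer(2), variant_monomer(3)
        d2, d3 = s2.__dict__.copy(), s3.__dict__.copy()
        assert d2.pop("inner_arm_class") != d3.pop("inner_arm_class")
        assert d2 == d3

    def test_charge_constant_across_variants(self):
        assert len({variant_monomer(v).dipole_charge for v in (1, 2, 3)}) == 1

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            variant_monomer(4)


class TestPairEnergy:
    def test_lj_root_at_sigma(self):
        assert pair_energy("C1", "C1", r=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_depth(self):
        r_min = 2.0 ** (1 / 6)
        assert pair_energy("N0", "N0", r=r_min) == pytest.approx(
            -eps_lookup("N0", "N0"), rel=1e-12
        )

    def test_opposite_charges_coulomb_attractive_one_over_r(self):
        # LJ negligible far outside the well
        e1 = pair_energy("DIP", "DIP", r=10.0, q_i=1.0, q_j=-1.0)
        e2 = pair_energy("DIP", "DIP", r=20.0, q_i=1.0, q_j=-1.0)
        assert e1 < 0
        assert e1 / e2 == pytest.approx(2.0, rel=1e-6)

    def test_symmetry_exact(self):
        for r in (0.8, 1.0, 1.7):
            assert pair_energy("C5", "N0", r) == pair_energy("N0", "C5", r)

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            pair_energy("C1", "C1", r=0.0)

    def test_solvophobicity_tier_orders_cross_interaction(self):
        # attraction to the solvophilic class strictly decreases with tier
        e_by_tier = [eps_lookup(c, "C1") for c in ("C1", "C5", "N0")]
        assert e_by_tier[0] > e_by_tier[1] > e_by_tier[2]


class TestDimerization:
    def test_negligible_charge_solvophilic_dimer_unbound(self):
        spec = MonomerSpec(inner_arm_class="C1", dipole_charge=1e-6)
        dg, err, info = dimerization_free_energy(
            spec, seed=3, n_windows=10, steps_per_window=1500, equil_steps=400
        )
        assert abs(dg) < max(3 * err, 0.5)

    def test_binding_strengthens_with_dipole_charge(self):
        kwargs = dict(n_windows=12, steps_per_window=2500, equil_steps=600)
        dg1, e1, _ = dimerization_free_energy(
            MonomerSpec(dipole_charge=1.0), seed=4, **kwargs
        )
        dg2, e2, _ = dimerization_free_energy(
            MonomerSpec(dipole_charge=2.0), seed=4, **kwargs
        )
        assert dg2 < dg1  # deeper (more negative) bound-state free energy
        assert e1 > 0 and e2 > 0  # error bars always reported

    def test_default_variant3_dimer_is_bound(self):
        dg, err, info = dimerization_free_energy(
            variant_monomer(3), seed=5, n_windows=12, steps_per_window=2000,
            equil_steps=500,
        )
        assert dg < 0
        assert "unreliable" in info
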