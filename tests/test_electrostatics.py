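"""Dipoles, skin potentials, Hodgkin similarity, clade clustering."""

import numpy as np
import pytest

from actinofam.electrostatics import (
    EA_TO_DEBYE,
    ChargedStructure,
    PotentialGrid,
    cluster_clades,
    coulomb_skin_grid,
    fragment_dipole,
    hodgkin_similarity,
    read_pqr,
    shared_lattice,
    similarity_distance,
    write_pqr,
)
from actinofam.errors import ParseError, StructureError
from actinofam.synthetic import make_clade_archetypes, synth_helix_charges


def two_point_structure(q1=1.0, q2=-1.0, z=0.5):
    return ChargedStructure(
        id="dip",
        residue_index=np.array([1, 2]),
        atom_names=["X1", "X2"],
        residue_names=["GLY", "GLY"],
        coords=np.array([[0.0, 0.0, z], [0.0, 0.0, -z]]),
        charges=np.array([q1, q2]),
        radii=np.array([1.0, 1.0]),
    )


class TestPqrIO:
    def test_two_atom_total_charge(self, tmp_path):
        p = tmp_path / "t.pqr"
        p.write_text(
            "ATOM 1 N ALA 1 0.0 0.0 0.0 -0.30 1.5\n"
            "ATOM 2 CA ALA 1 1.0 0.0 0.0 0.45 2.0\n"
        )
        s = read_pqr(p)
        assert s.total_charge == pytest.approx(0.15)
        assert s.n_atoms == 2

    def test_missing_field_names_line(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 N ALA 1 0.0 0.0 0.0 -0.30\n")
        with pytest.raises(ParseError, match="bad.pqr:1"):
            read_pqr(p)

    def test_no_atoms_rejected(self, tmp_path):
        p = tmp_path / "e.pqr"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(ParseError):
            read_pqr(p)

    def test_helix_round_trips_bit_identically(self, tmp_path):
        s = synth_helix_charges([0.5, -0.5, 0.25] * 9, structure_id="h", noise=0.1, seed=4)
        p1 = tmp_path / "a.pqr"
        p2 = tmp_path / "b.pqr"
        write_pqr(s, p1)
        write_pqr(read_pqr(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestFragmentDipole:
    def test_unit_dipole(self):
        d = fragment_dipole(two_point_structure(), fragment=(1, 2))
        assert d.magnitude_debye == pytest.approx(EA_TO_DEBYE, abs=1e-12)
        assert d.direction == pytest.approx([0.0, 0.0, 1.0])

    def test_zero_charges_flagged_undefined(self):
        d = fragment_dipole(two_point_structure(0.0, 0.0), fragment=(1, 2))
        assert d.magnitude_debye == 0.0
        assert d.direction is None

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        s = ChargedStructure(
            id="r",
            residue_index=np.arange(1, n + 1),
            atom_names=["X"] * n,
            residue_names=["GLY"] * n,
            coords=rng.normal(size=(n, 3)) * 5,
            charges=rng.normal(size=n),
            radii=np.full(n, 1.5),
        )
        d = fragment_dipole(s, fragment=(1, n))
        origin = s.coords.mean(axis=0)
        mu = np.zeros(3)
        for k in range(n):  # explicit per-atom summation oracle
            mu += s.charges[k] * (s.coords[k] - origin)
        assert d.magnitude_debye == pytest.approx(
            np.linalg.norm(mu) * EA_TO_DEBYE, rel=1e-12
        )
        assert d.direction == pytest.approx(mu / np.linalg.norm(mu), rel=1e-9)

    def test_translation_invariance(self):
        s = synth_helix_charges([0.4, -0.4] * 10, structure_id="h")
        shifted = ChargedStructure(
            id="h2",
            residue_index=s.residue_index,
            atom_names=s.atom_names,
            residue_names=s.residue_names,
            coords=s.coords + np.array([11.0, -3.0, 7.0]),
            charges=s.charges,
            radii=s.radii,
        )
        d1 = fragment_dipole(s, (1, 20))
        d2 = fragment_dipole(shifted, (1, 20))
        assert d1.magnitude_debye == pytest.approx(d2.magnitude_debye, rel=1e-9)
        assert d1.direction == pytest.approx(d2.direction, rel=1e-9)

    def test_origin_shift_changes_moment_by_minus_q_delta(self):
        """For a charged fragment, mu(O') = mu(O) - Q (O' - O)."""
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(10, 3))
        q = rng.uniform(0.1, 0.5, size=10)  # net positive
        com = coords.mean(axis=0)
        delta = np.array([1.0, 2.0, -0.5])
        mu_com = (q[:, None] * (coords - com)).sum(axis=0)
        mu_shift = (q[:, None] * (coords - (com + delta))).sum(axis=0)
        assert mu_shift == pytest.approx(mu_com - q.sum() * delta, rel=1e-12)

    def test_rotation_equivariance(self):
        layout = [0.5, -0.3, 0.2] * 9
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        d0 = fragment_dipole(synth_helix_charges(layout), (1, 27))
        dr = fragment_dipole(
            synth_helix_charges(layout, orientation=rot), (1, 27)
        )
        assert dr.magnitude_debye == pytest.approx(d0.magnitude_debye, rel=1e-9)
        assert dr.direction == pytest.approx(rot @ d0.direction, abs=1e-9)

    def test_empty_fragment_rejected(self):
        with pytest.raises(StructureError):
            fragment_dipole(two_point_structure(), fragment=(5, 9))


class TestSkinGrid:
    def test_single_charge_monotone_decay(self):
        s = ChargedStructure(
            id="pt",
            residue_index=np.array([1]),
            atom_names=["X"],
            residue_names=["GLY"],
            coords=np.zeros((1, 3)),
            charges=np.array([1.0]),
            radii=np.array([2.0]),
        )
        g = coulomb_skin_grid(s, spacing=1.0)
        # recover point coordinates to sort by distance
        idx = np.unravel_index(g.skin_index, g.dims)
        pts = g.origin + g.spacing * np.stack(idx, axis=1)
        r = np.linalg.norm(pts, axis=1)
        order = np.argsort(r)
        phi = g.potential[order]
        assert np.all(np.diff(phi) <= 1e-12)

    def test_negated_charges_negate_grid(self):
        s1 = synth_helix_charges([0.5, -0.2] * 8, structure_id="a")
        s2 = ChargedStructure(
            id="b",
            residue_index=s1.residue_index,
            atom_names=s1.atom_names,
            residue_names=s1.residue_names,
            coords=s1.coords,
            charges=-s1.charges,
            radii=s1.radii,
        )
        lat = shared_lattice([s1], 1.0, margin=8.0)
        g1 = coulomb_skin_grid(s1, lattice=lat)
        g2 = coulomb_skin_grid(s2, lattice=lat)
        assert np.array_equal(g1.skin_index, g2.skin_index)
        assert g1.potential == pytest.approx(-g2.potential, rel=1e-12)

    def test_superposition_of_two_atoms(self):
        def point(q, pos, sid):
            return ChargedStructure(
                id=sid,
                residue_index=np.array([1]),
                atom_names=["X"],
                residue_names=["GLY"],
                coords=np.array([pos]),
                charges=np.array([q]),
                radii=np.array([1.5]),
            )

        a = point(0.8, [0.0, 0.0, 0.0], "a")
        b = point(-0.5, [4.0, 0.0, 0.0], "b")
        both = ChargedStructure(
            id="ab",
            residue_index=np.array([1, 2]),
            atom_names=["X", "X"],
            residue_names=["GLY", "GLY"],
            coords=np.vstack([a.coords, b.coords]),
            charges=np.array([0.8, -0.5]),
            radii=np.array([1.5, 1.5]),
        )
        lat = shared_lattice([both], 1.0, margin=8.0)
        ga = coulomb_skin_grid(a, lattice=lat)
        gb = coulomb_skin_grid(b, lattice=lat)
        gab = coulomb_skin_grid(both, lattice=lat)
        da, db, dab = ga.as_dict(), gb.as_dict(), gab.as_dict()
        common = set(da) & set(db) & set(dab)
        assert common
        for i in common:
            assert dab[i] == pytest.approx(da[i] + db[i], rel=1e-12)

    def test_degenerate_skin_rejected(self):
        s = two_point_structure()
        with pytest.raises(ValueError):
            coulomb_skin_grid(s, skin=(7.0, 3.0))


class TestHodgkin:
    def _grid(self, values, index=None):
        values = np.asarray(values, dtype=float)
        return PotentialGrid(
            origin=np.zeros(3),
            spacing=1.0,
            dims=(4, 4, 4),
            potential=values,
            skin_index=np.arange(len(values)) if index is None else np.asarray(index),
        )

    def test_self_similarity_one(self):
        g = self._grid([1.0, -2.0, 0.5])
        assert hodgkin_similarity(g, g) == pytest.approx(1.0)
        assert similarity_distance(1.0) == 0.0

    def test_negation_minus_one(self):
        g = self._grid([1.0, -2.0, 0.5])
        gn = self._grid([-1.0, 2.0, -0.5])
        si = hodgkin_similarity(g, gn)
        assert si == pytest.approx(-1.0)
        assert similarity_distance(si) == pytest.approx(2.0)

    def test_orthogonal_fields_zero(self):
        g1 = self._grid([1.0, 0.0, 3.0, 0.0])
        g2 = self._grid([0.0, 2.0, 0.0, -1.0])
        si = hodgkin_similarity(g1, g2)
        assert si == pytest.approx(0.0)
        assert similarity_distance(si) == pytest.approx(np.sqrt(2.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v1, v2 = rng.normal(size=30), rng.normal(size=30)
        si = hodgkin_similarity(self._grid(v1), self._grid(v2))
        si_scaled = hodgkin_similarity(self._grid(3.7 * v1), self._grid(3.7 * v2))
        assert si_scaled == pytest.approx(si, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetric_bounded_triangle(self, seed):
        rng = np.random.default_rng(seed)
        grids = [self._grid(rng.normal(size=25)) for _ in range(3)]
        sis = {}
        for i in range(3):
            for j in range(3):
                sis[(i, j)] = hodgkin_similarity(grids[i], grids[j])
        for i in range(3):
            for j in range(3):
                assert sis[(i, j)] == pytest.approx(sis[(j, i)], rel=1e-12)
                assert -1.0 - 1e-12 <= sis[(i, j)] <= 1.0 + 1e-12
        d01 = similarity_distance(sis[(0, 1)])
        d12 = similarity_distance(sis[(1, 2)])
        d02 = similarity_distance(sis[(0, 2)])
        assert d02 <= d01 + d12 + 1e-12

    def test_mismatched_lattice_rejected(self):
        g1 = self._grid([1.0, 2.0])
        g2 = PotentialGrid(
            origin=np.ones(3), spacing=1.0, dims=(4, 4, 4),
            potential=np.array([1.0, 2.0]), skin_index=np.array([0, 1]),
        )
        with pytest.raises(StructureError):
            hodgkin_similarity(g1, g2)


class TestCladeClustering:
    def test_three_archetypes_recovered(self):
        structures, truth = make_clade_archetypes(n_replicates=4, seed=3)
        result = cluster_clades(structures, k=3, spacing=1.5)
        # each recovered clade must contain exactly one archetype
        from collections import defaultdict

        members = defaultdict(set)
        for sid, clade in result.labels.items():
            members[clade].add(truth[sid])
        assert len(members) == 3
        assert all(len(v) == 1 for v in members.values())

    def test_identical_structures_single_clade(self):
        s = [
            synth_helix_charges([0.5, -0.5] * 5, structure_id=f"s{i}")
            for i in range(3)
        ]
        result = cluster_clades(s, k=1, spacing=1.5)
        assert set(result.labels.values()) == {"Clade I"}

    def test_assignment_invariant_to_input_order(self):
        structures, _ = make_clade_archetypes(n_replicates=3, seed=5)
        r1 = cluster_clades(structures, k=3, spacing=1.5)
        r2 = cluster_clades(list(reversed(structures)), k=3, spacing=1.5)
        assert r1.labels == r2.labels

    def test_too_few_structures_rejected(self):
        s = [synth_helix_charges([0.5] * 5, structure_id="x")]
        with pytest.raises(StructureError):
            cluster_clades(s, k=3)

    def test_similarity_matrix_diagonal_one(self):
        structures, _ = make_clade_archetypes(n_replicates=3, seed=2)
        result = cluster_clades(structures, k=3, spacing=1.5)
        assert np.diag(result.similarity.values) == pytest.approx(1.0)
        assert result.similarity.values.min() >= -1.0 - 1e-9
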