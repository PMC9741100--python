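"""Point-charge electrostatics, solvation shells and g(r)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmmfep import (
    EnvironmentFrame,
    InvariantError,
    SingularGeometryError,
    UnsupportedBoxError,
    filter_shell,
    potential_and_field,
    radial_distribution,
    read_gro_frames,
    read_xyz_frames,
    sample_perturbation,
)
from pmmfep.environment import read_charge_table
from pmmfep.units import ANGSTROM_TO_BOHR

from conftest import random_frame


def frame_of(charges, positions, box=None, mol_ids=None):
    charges = np.asarray(charges, dtype=float)
    return EnvironmentFrame(
        charges=charges,
        positions=np.asarray(positions, dtype=float),
        molecule_ids=np.arange(len(charges)) if mol_ids is None else np.asarray(mol_ids),
        box=box,
    )


class TestPotentialAndField:
    def test_single_unit_charge_coulomb_law(self):
        """+1 e at 2 bohr gives V = 1/2 and |E| = 1/4 a.u."""
        r = 2.0 / ANGSTROM_TO_BOHR  # Å
        frame = frame_of([1.0], [[r, 0.0, 0.0]])
        v, e = potential_and_field(frame, [0.0, 0.0, 0.0])
        assert v == pytest.approx(0.5, rel=1e-12)
        assert np.linalg.norm(e) == pytest.approx(0.25, rel=1e-12)
        assert e[0] == pytest.approx(-0.25, rel=1e-12)  # field points away from the charge

    def test_symmetric_pair_cancels_field_doubles_potential(self):
        frame1 = frame_of([1.0], [[3.0, 0.0, 0.0]])
        frame2 = frame_of([1.0, 1.0], [[3.0, 0.0, 0.0], [-3.0, 0.0, 0.0]])
        v1, _ = potential_and_field(frame1, [0.0, 0.0, 0.0])
        v2, e2 = potential_and_field(frame2, [0.0, 0.0, 0.0])
        assert v2 == pytest.approx(2 * v1, rel=1e-12)
        assert np.allclose(e2, 0.0, atol=1e-15)

    def test_minimum_image_matches_nearest_image_enumeration(self, rng):
        """Direct MI sum equals a brute-force scan over all 27 image copies."""
        box = np.array([12.0, 15.0, 9.0])
        frame = random_frame(rng, n=100, box=box)
        point = np.array([6.0, 7.0, 4.0])
        v, e = potential_and_field(frame, point)
        # oracle: for every charge pick the closest of its 27 periodic images
        shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
        v_ref, e_ref = 0.0, np.zeros(3)
        for q, pos in zip(frame.charges, frame.positions):
            images = pos[None, :] + shifts * box[None, :]
            d = point[None, :] - images
            r = np.linalg.norm(d, axis=1)
            m = np.argmin(r)
            rb = r[m] * ANGSTROM_TO_BOHR
            v_ref += q / rb
            e_ref += q * d[m] * ANGSTROM_TO_BOHR / rb**3
        assert v == pytest.approx(v_ref, abs=1e-10)
        assert np.allclose(e, e_ref, atol=1e-10)

    def test_periodic_equals_direct_within_quarter_box(self, rng):
        box = np.array([40.0, 40.0, 40.0])
        point = box / 2
        positions = point + rng.uniform(-9.0, 9.0, (30, 3))  # all within a quarter box
        charges = rng.uniform(-1, 1, 30)
        periodic = frame_of(charges, positions, box=box)
        direct = frame_of(charges, positions)
        vp, ep = potential_and_field(periodic, point)
        vd, ed = potential_and_field(direct, point)
        assert vp == pytest.approx(vd, rel=1e-14)
        assert np.allclose(ep, ed, rtol=1e-14)

    def test_clash_names_the_particle(self):
        frame = frame_of([1.0, 1.0], [[5.0, 0.0, 0.0], [0.01, 0.0, 0.0]])
        with pytest.raises(SingularGeometryError, match="particle 1"):
            potential_and_field(frame, [0.0, 0.0, 0.0])

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_linearity_and_charge_antisymmetry(self, seed):
        """Superposition over frames; negating charges negates V and E."""
        rng = np.random.default_rng(seed)
        a = random_frame(rng, n=20)
        b = random_frame(rng, n=15)
        point = np.array([30.0, 30.0, 30.0])  # outside both charge clouds
        union = frame_of(
            np.concatenate([a.charges, b.charges]),
            np.concatenate([a.positions, b.positions]),
        )
        va, ea = potential_and_field(a, point)
        vb, eb = potential_and_field(b, point)
        vu, eu = potential_and_field(union, point)
        assert vu == pytest.approx(va + vb, rel=1e-12, abs=1e-15)
        assert np.allclose(eu, ea + eb, rtol=1e-12, atol=1e-18)
        neg = frame_of(-a.charges, a.positions)
        vn, en = potential_and_field(neg, point)
        assert vn == pytest.approx(-va, rel=1e-14, abs=1e-18)
        assert np.allclose(en, -ea, rtol=1e-14, atol=1e-20)


class TestSamplePerturbation:
    def test_empty_frame_gives_zero_sample(self):
        frame = frame_of([], np.zeros((0, 3)))
        s = sample_perturbation(frame, np.array([[0.0, 0, 0], [1.5, 0, 0]]), ["S", "O"])
        assert np.all(s.potential_at_atoms == 0)
        assert np.all(s.field_at_origin == 0)
        assert s.potential_at_origin == 0

    def test_equidistant_charge_gives_equal_atom_potentials(self):
        geometry = np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        frame = frame_of([0.7], [[0.0, 4.0, 0.0]])
        s = sample_perturbation(frame, geometry, ["O", "O"])
        assert s.potential_at_atoms[0] == pytest.approx(s.potential_at_atoms[1], rel=1e-14)

    def test_origin_potential_consistent_with_direct_call(self, rng):
        from pmmfep.environment import center_of_mass

        frame = random_frame(rng, n=25)
        geometry = np.array([[30.0, 30, 30], [31.5, 30, 30], [30.5, 31, 30]])
        elements = ["S", "O", "H"]
        s = sample_perturbation(frame, geometry, elements)
        v0, e0 = potential_and_field(frame, center_of_mass(geometry, elements))
        assert s.potential_at_origin == pytest.approx(v0, rel=1e-14)
        assert np.allclose(s.field_at_origin, e0, rtol=1e-14)


class TestFilterShell:
    def water_like_frame(self, nearest_distance):
        """One 3-site molecule whose nearest atom is at the given distance."""
        base = np.array([nearest_distance, 0.0, 0.0])
        positions = np.stack([base, base + [0.6, 0.4, 0], base + [0.6, -0.4, 0]])
        return frame_of([-0.8, 0.4, 0.4], positions, mol_ids=[5, 5, 5])

    def test_molecule_at_5p4_kept_by_5p5_shell(self):
        kept = filter_shell(self.water_like_frame(5.4), [0, 0, 0], r_shell=5.5)
        assert kept.n_particles == 3  # whole molecule, never split

    def test_molecule_at_5p6_removed(self):
        kept = filter_shell(self.water_like_frame(5.6), [0, 0, 0], r_shell=5.5)
        assert kept.n_particles == 0

    def test_kept_and_complement_partition_the_frame(self, rng):
        frame = random_frame(rng, n=60, box=[20.0, 20.0, 20.0])
        frame.molecule_ids //= 3  # 3-particle molecules
        center = np.array([10.0, 10.0, 10.0])
        kept = filter_shell(frame, center, r_shell=6.0)
        excl = filter_shell(frame, center, r_shell=6.0, complement=True)
        assert kept.n_particles + excl.n_particles == frame.n_particles
        merged = np.sort(np.concatenate([kept.positions, excl.positions]), axis=0)
        assert np.array_equal(merged, np.sort(frame.positions, axis=0))

    def test_idempotent(self, rng):
        frame = random_frame(rng, n=40, box=[20.0, 20.0, 20.0])
        center = np.array([10.0, 10.0, 10.0])
        once = filter_shell(frame, center, r_shell=5.5)
        twice = filter_shell(once, center, r_shell=5.5)
        assert np.array_equal(once.positions, twice.positions)
        assert np.array_equal(once.charges, twice.charges)


class TestRadialDistribution:
    def test_ideal_gas_is_uniform(self, rng):
        """Uniform random particles give g(r) = 1 within 3 SE per bin."""
        box = np.array([20.0, 20.0, 20.0])
        n, n_frames = 400, 200
        frames = [random_frame(rng, n=n, box=box) for _ in range(n_frames)]
        res = radial_distribution(frames, box / 2, bin_width=0.5, r_max=8.0)
        rho = n / box.prod()
        shell = 4 / 3 * np.pi * ((res.r + 0.25) ** 3 - (res.r - 0.25) ** 3)
        expected_counts = rho * shell * n_frames
        se = np.sqrt(expected_counts) / expected_counts  # Poisson, relative
        assert np.all(np.abs(res.g - 1.0) < 3 * np.maximum(se, 1e-3) + 0.02)

    def test_single_particle_lands_in_its_bin(self):
        frame = frame_of([1.0], [[13.0, 10.0, 10.0]], box=np.array([40.0, 40.0, 40.0]),
                         mol_ids=[0])
        frame.positions[0] = [13.0, 10.0, 10.0]
        res = radial_distribution([frame], [10.0, 10.0, 10.0], bin_width=0.5, r_max=10.0)
        assert res.counts.sum() == 1
        assert res.counts[np.digitize(3.0, np.arange(0, 10.5, 0.5)) - 1] == 1

    def test_first_shell_coordination_number(self, rng):
        """A synthetic solvent with 17 particles inside 5.5 Å has n(5.5) ≈ 17."""
        box = np.array([30.0, 30.0, 30.0])
        center = box / 2
        frames = []
        for _ in range(150):
            # 17 first-shell particles between 2.5 and 5.3 Å, plus distant bulk
            r = rng.uniform(2.5, 5.3, 17)
            u = rng.normal(size=(17, 3))
            u /= np.linalg.norm(u, axis=1)[:, None]
            shell_pos = center + u * r[:, None]
            bulk = center + rng.uniform(8.0, 12.0, (40, 3)) * rng.choice([-1, 1], (40, 3))
            positions = np.vstack([shell_pos, bulk[np.linalg.norm(bulk - center, axis=1) < 14]])
            m = len(positions)
            frames.append(frame_of(np.ones(m), positions, box=box, mol_ids=np.arange(m)))
        res = radial_distribution(frames, center, bin_width=0.25, r_max=10.0)
        n_at_shell = res.coordination[np.searchsorted(res.r + 0.125, 5.5)]
        assert n_at_shell == pytest.approx(17.0, abs=0.5)

    def test_r_max_beyond_half_box_rejected(self, rng):
        frames = [random_frame(rng, n=10, box=[12.0, 12.0, 12.0])]
        with pytest.raises(InvariantError, match="half the smallest box"):
            radial_distribution(frames, [6.0, 6.0, 6.0], bin_width=0.5, r_max=7.0)


class TestReaders:
    def write_charge_table(self, path, charges, mol_ids):
        lines = ["# index charge molecule_id"]
        for i, (q, m) in enumerate(zip(charges, mol_ids)):
            lines.append(f"{i} {q} {m}")
        path.write_text("\n".join(lines) + "\n")

    def test_xyz_round_trip(self, tmp_path):
        xyz = tmp_path / "traj.xyz"
        xyz.write_text(
            "3\nframe 0\nO 1.0 2.0 3.0\nH 1.5 2.0 3.0\nH 0.5 2.0 3.0\n"
            "3\nframe 1\nO 1.1 2.0 3.0\nH 1.6 2.0 3.0\nH 0.6 2.0 3.0\n"
        )
        table = tmp_path / "charges.txt"
        self.write_charge_table(table, [-0.8, 0.4, 0.4], [0, 0, 0])
        frames = read_xyz_frames(xyz, table, box=[15.0, 15.0, 15.0])
        assert len(frames) == 2
        assert frames[0].positions[0] == pytest.approx([1.0, 2.0, 3.0])
        assert frames[1].positions[0] == pytest.approx([1.1, 2.0, 3.0])
        assert frames[0].charges == pytest.approx([-0.8, 0.4, 0.4])
        assert np.array_equal(frames[0].box, [15.0, 15.0, 15.0])

    def test_gro_reads_box_line(self, tmp_path):
        gro = tmp_path / "conf.gro"
        gro.write_text(
            "water\n"
            "    3\n"
            "    1SOL     OW    1   0.100   0.200   0.300\n"
            "    1SOL    HW1    2   0.150   0.200   0.300\n"
            "    1SOL    HW2    3   0.050   0.200   0.300\n"
            "   1.50000   1.50000   1.50000\n"
        )
        table = tmp_path / "charges.txt"
        self.write_charge_table(table, [-0.8, 0.4, 0.4], [0, 0, 0])
        frames = read_gro_frames(gro, table)
        assert len(frames) == 1
        # GRO is in nm; frames are in Å
        assert frames[0].positions[0] == pytest.approx([1.0, 2.0, 3.0], abs=1e-3)
        assert frames[0].box == pytest.approx([15.0, 15.0, 15.0], abs=1e-3)

    def test_triclinic_box_rejected(self, tmp_path):
        gro = tmp_path / "tric.gro"
        gro.write_text(
            "triclinic\n"
            "    1\n"
            "    1SOL     OW    1   0.100   0.200   0.300\n"
            "   1.50000   1.50000   1.50000   0.00000   0.00000   0.50000"
            "   0.00000   0.00000   0.00000\n"
        )
        table = tmp_path / "charges.txt"
        self.write_charge_table(table, [-0.8], [0])
        with pytest.raises(UnsupportedBoxError):
            read_gro_frames(gro, table)

    def test_charge_table_index_gaps_rejected(self, tmp_path):
        table = tmp_path / "bad.txt"
        table.write_text("0 0.5 0\n2 -0.5 1\n")
        with pytest.raises(InvariantError, match="0..P-1"):
            read_charge_table(table)
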