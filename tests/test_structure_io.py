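import numpy as np
import pytest
import gemmi

from seqregister.structure_io import (Chain, DensityMap, MapCoefficients, ParseError,
                                      Residue, StructureModel, TargetSequence,
                                      continuous_runs, interpolate, model_sequence,
                                      read_map_or_coefficients, read_sequences,
                                      read_structure, synthesize_map, write_map,
                                      write_sequences, write_structure)

from conftest import make_chain


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class TestStructures:
    def test_round_trip_two_chain_fixture(self, two_chain_model, tmp_path):
        path = tmp_path / "m.pdb"
        write_structure(two_chain_model, str(path))
        model = read_structure(str(path))
        sizes = {c.id: len(c) for c in model.protein_chains()}
        assert sizes == {"A": 30, "B": 10}

    def test_unk_residue_maps_to_x(self, tmp_path):
        chain = make_chain(["ALA", "UNK", "GLY"], with_atoms=True)
        model = StructureModel(chains=[chain], cell=(30, 20, 20, 90, 90, 90))
        path = tmp_path / "m.pdb"
        write_structure(model, str(path))
        res = read_structure(str(path)).get_chain("A").residues[1]
        assert res.type3 == "UNK" and res.type1 == "X"

    def test_mmcif_and_pdb_agree(self, two_chain_model, tmp_path):
        """Cross-format oracle: both encodings give the same listing."""
        p1, p2 = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_structure(two_chain_model, str(p1))
        write_structure(two_chain_model, str(p2))
        m1, m2 = read_structure(str(p1)), read_structure(str(p2))
        listing = lambda m: [
            (c.id, [(r.number, r.icode, r.type3) for r in c.residues]) for c in m.chains
        ]
        assert listing(m1) == listing(m2)

    def test_round_trip_preserves_numbering_and_icodes(self, tmp_path):
        chain = make_chain(["ALA", "GLY", "SER"], numbers=[5, 5, 7],
                           icodes=["", "A", ""], with_atoms=True)
        model = StructureModel(chains=[chain], cell=(30, 20, 20, 90, 90, 90))
        path = tmp_path / "m.pdb"
        write_structure(model, str(path))
        back = read_structure(str(path)).get_chain("A")
        assert [(r.number, r.icode, r.type3) for r in back.residues] == \
            [(5, "", "ALA"), (5, "A", "GLY"), (7, "", "SER")]

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "junk.pdb"
        bad.write_text("this is not a coordinate file\n")
        with pytest.raises((ParseError, ValueError)):
            read_structure(str(bad))

    def test_chain_ordering_invariant(self):
        with pytest.raises(ValueError):
            make_chain(["ALA", "GLY"], numbers=[7, 7])


class TestModelSequence:
    def test_basic(self):
        chain = make_chain(["ALA", "GLY", "SER"], numbers=[10, 11, 12])
        assert model_sequence(chain) == ("AGS", [10, 11, 12], True)

    def test_numbering_gap_breaks_continuity(self):
        chain = make_chain(["ALA", "GLY", "SER"], numbers=[10, 11, 13])
        seq, nums, cont = model_sequence(chain)
        assert seq == "AGS" and not cont

    def test_icode_breaks_continuity(self):
        chain = make_chain(["ALA", "GLY"], numbers=[10, 10], icodes=["", "A"])
        assert model_sequence(chain)[2] is False

    def test_unk_gives_x(self):
        chain = make_chain(["ALA", "UNK", "SER"])
        assert model_sequence(chain)[0] == "AXS"

    def test_continuous_runs_split_on_gaps_and_icodes(self):
        chain = make_chain(["ALA"] * 6, numbers=[1, 2, 3, 7, 8, 9])
        assert continuous_runs(chain) == [(0, 2), (3, 5)]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

class TestSequences:
    def test_single_record(self, tmp_path):
        p = tmp_path / "s.fasta"
        p.write_text(">s1\nACDEFG\n")
        seqs = read_sequences(str(p))
        assert [(s.id, s.residues) for s in seqs] == [("s1", "ACDEFG")]

    def test_wrapped_and_lowercase_and_terminator(self, tmp_path):
        p = tmp_path / "s.fasta"
        p.write_text(">s1\nacd\nEFG*\n")
        assert read_sequences(str(p))[0].residues == "ACDEFG"

    def test_illegal_character_names_record_and_position(self, tmp_path):
        p = tmp_path / "s.fasta"
        p.write_text(">s1\nACBDE\n")
        with pytest.raises(ParseError, match="s1.*position 3"):
            read_sequences(str(p))

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "s.fasta"
        p.write_text(">s1\nACD\n>s1\nGHI\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_sequences(str(p))

    def test_write_read_round_trip(self, tmp_path):
        seqs = [TargetSequence("a", "ACDEFGHIKLMNPQRSTVWYX" * 5),
                TargetSequence("b", "GGG")]
        p = tmp_path / "out.fasta"
        write_sequences(seqs, str(p))
        back = read_sequences(str(p))
        assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]


# ---------------------------------------------------------------------------
# maps and coefficients
# ---------------------------------------------------------------------------

def point_scatterer_coeffs(cell, frac_pos, hmax=4, sigma=0.8):
    """Analytic Fourier coefficients of one Gaussian atom in a P1 cell."""
    hs = []
    amps = []
    phases = []
    frac = np.asarray(frac_pos)
    u = gemmi.UnitCell(*cell)
    recip = np.array(u.frac.mat.tolist())
    for h in range(-hmax, hmax + 1):
        for k in range(-hmax, hmax + 1):
            for l in range(-hmax, hmax + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                s2 = float(np.sum((np.array([h, k, l]) @ recip) ** 2))
                amp = np.exp(-2 * np.pi**2 * sigma**2 * s2)
                phase = np.rad2deg(2 * np.pi * float(np.dot([h, k, l], frac))) % 360.0
                hs.append((h, k, l))
                amps.append(amp)
                phases.append(phase)
    return MapCoefficients(hkl=np.array(hs), amplitude=np.array(amps),
                           phase=np.array(phases), labels=("FWT", "PHWT"), cell=cell)


def write_mtz(coeffs, path):
    mtz = gemmi.Mtz(with_base=True)
    mtz.cell = gemmi.UnitCell(*coeffs.cell)
    mtz.spacegroup = gemmi.find_spacegroup_by_name("P1")
    mtz.add_dataset("synthetic")
    mtz.add_column("FWT", "F")
    mtz.add_column("PHWT", "P")
    data = np.column_stack([coeffs.hkl.astype(float), coeffs.amplitude, coeffs.phase])
    mtz.set_data(data.astype(np.float32))
    mtz.write_to_file(str(path))


class TestMaps:
    cell = (20.0, 18.0, 16.0, 90.0, 90.0, 90.0)

    def test_point_scatterer_peak_position(self, tmp_path):
        frac = (0.3, 0.55, 0.2)
        coeffs = point_scatterer_coeffs(self.cell, frac)
        p = tmp_path / "c.mtz"
        write_mtz(coeffs, p)
        dmap = read_map_or_coefficients(str(p))
        peak = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
        expect = [round(f * n) % n for f, n in zip(frac, dmap.grid.shape)]
        assert list(peak) == expect

    def test_normalization(self, tmp_path):
        coeffs = point_scatterer_coeffs(self.cell, (0.1, 0.2, 0.3))
        p = tmp_path / "c.mtz"
        write_mtz(coeffs, p)
        dmap = read_map_or_coefficients(str(p))
        assert abs(dmap.grid.mean()) < 1e-6
        assert abs(dmap.grid.std() - 1.0) < 1e-6

    def test_mtz_vs_direct_gaussian_sum(self):
        """Fourier synthesis against a direct-space periodic Gaussian sum."""
        rng = np.random.default_rng(5)
        fracs = rng.random((5, 3))
        sigma = 1.4  # smooth enough that the truncated series carries ~all power
        coeff_list = [point_scatterer_coeffs(self.cell, f, hmax=5, sigma=sigma)
                      for f in fracs]
        total = MapCoefficients(
            hkl=coeff_list[0].hkl,
            amplitude=np.abs(sum(c.amplitude * np.exp(1j * np.deg2rad(c.phase))
                                 for c in coeff_list)),
            phase=np.rad2deg(np.angle(sum(c.amplitude * np.exp(1j * np.deg2rad(c.phase))
                                          for c in coeff_list))) % 360.0,
            labels=("FWT", "PHWT"), cell=self.cell)
        dmap = synthesize_map(total, grid_spacing=0.5)
        # direct-space oracle on the same grid
        dims = dmap.grid.shape
        axes = [np.arange(n) / n for n in dims]
        direct = np.zeros(dims)
        lengths = np.array(self.cell[:3])
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        for f in fracs:
            dx = (gx - f[0] + 0.5) % 1.0 - 0.5
            dy = (gy - f[1] + 0.5) % 1.0 - 0.5
            dz = (gz - f[2] + 0.5) % 1.0 - 0.5
            r2 = (dx * lengths[0]) ** 2 + (dy * lengths[1]) ** 2 + (dz * lengths[2]) ** 2
            direct += np.exp(-r2 / (2 * sigma**2))
        corr = np.corrcoef(dmap.grid.ravel(), direct.ravel())[0, 1]
        assert corr > 0.99

    def test_synthesis_linearity(self):
        coeffs = point_scatterer_coeffs(self.cell, (0.4, 0.1, 0.7))
        import dataclasses
        scaled = dataclasses.replace(coeffs, amplitude=3.0 * coeffs.amplitude)
        m1 = synthesize_map(coeffs, normalize=False)
        m3 = synthesize_map(scaled, normalize=False)
        assert np.allclose(m3.grid, 3.0 * m1.grid, atol=1e-8)

    def test_missing_labels_error_lists_available(self, tmp_path):
        coeffs = point_scatterer_coeffs(self.cell, (0.1, 0.1, 0.1))
        p = tmp_path / "c.mtz"
        write_mtz(coeffs, p)
        with pytest.raises(ParseError, match="FWT"):
            read_map_or_coefficients(str(p), labels=("FOO", "BAR"))

    def test_ccp4_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        dmap = DensityMap(grid=rng.normal(size=(8, 10, 12)), cell=self.cell).normalized()
        p = tmp_path / "m.ccp4"
        write_map(dmap, str(p))
        back = read_map_or_coefficients(str(p))
        assert np.allclose(back.grid, dmap.grid, atol=1e-5)


class TestInterpolation:
    def make_map(self, seed=0, dims=(8, 9, 10)):
        rng = np.random.default_rng(seed)
        return DensityMap(grid=rng.normal(size=dims), cell=(16.0, 18.0, 20.0, 90, 90, 90))

    def test_exact_at_grid_nodes(self):
        dmap = self.make_map()
        dims = dmap.grid.shape
        cell = np.array(dmap.cell[:3])
        for idx in [(0, 0, 0), (3, 4, 5), (7, 8, 9)]:
            pos = np.array(idx) / dims * cell
            assert interpolate(dmap, pos) == pytest.approx(dmap.grid[idx], abs=1e-12)

    def test_midpoint_is_mean_of_neighbours(self):
        dmap = self.make_map()
        cell = np.array(dmap.cell[:3])
        dims = dmap.grid.shape
        pos = np.array([2.5, 4, 5]) / dims * cell
        expect = 0.5 * (dmap.grid[2, 4, 5] + dmap.grid[3, 4, 5])
        assert interpolate(dmap, pos) == pytest.approx(expect, abs=1e-12)

    def test_against_corner_weight_oracle(self):
        """1000 random positions vs brute-force 8-corner weighted sum."""
        dmap = self.make_map(seed=3)
        dims = np.array(dmap.grid.shape)
        cell = np.array(dmap.cell[:3])
        rng = np.random.default_rng(4)
        pos = rng.random((1000, 3)) * cell * 1.5  # beyond the cell: wraps
        got = interpolate(dmap, pos)
        for p, g in zip(pos, got):
            frac = p / cell
            gidx = frac * dims
            i0 = np.floor(gidx).astype(int)
            w = gidx - i0
            val = 0.0
            for bx in (0, 1):
                for by in (0, 1):
                    for bz in (0, 1):
                        wt = ((w[0] if bx else 1 - w[0])
                              * (w[1] if by else 1 - w[1])
                              * (w[2] if bz else 1 - w[2]))
                        idx = (i0 + [bx, by, bz]) % dims
                        val += wt * dmap.grid[tuple(idx)]
            assert abs(val - g) < 1e-10
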