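"""Phantom assembly, compartment masses and the voxel-list text format."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import embryodose as ed
from embryodose.phantom import CHROMATIN, EMBRYO_ONLY, NUCLEUS, P1_NUCLEUS


def _tiny_masks():
    """A 6×6×6 grid with a 2-voxel chromatin core inside a nucleus."""
    embryo = np.zeros((6, 6, 6), bool)
    embryo[1:5, 1:5, 1:5] = True
    ab = np.zeros_like(embryo)
    ab[2:4, 2:4, 2:4] = True
    chrom = np.zeros_like(embryo)
    chrom[2, 2, 2:4] = True
    p1 = np.zeros_like(embryo)
    p1[4, 4, 4] = True
    return embryo, ab, p1, chrom


class TestBuildPhantom:
    def test_generator_masks_need_no_reassignment(self, default_masks):
        ph = ed.phantom_from_masks(default_masks)
        assert ph.reassigned_chromatin_voxels == 0
        assert not (ph.compartment_mask("chromatin")
                    & ~ph.compartment_mask("nucleus")).any()
        assert not (ph.compartment_mask("nucleus")
                    & ~ph.compartment_mask("embryo")).any()

    def test_stray_chromatin_reassigned_and_counted(self):
        embryo, ab, p1, chrom = _tiny_masks()
        chrom[1, 1, 1] = True  # outside the nucleus, inside the embryo
        ph = ed.build_phantom(embryo, {"ab": ab, "p1": p1}, chrom,
                              pitch=(1.0, 1.0, 1.0))
        assert ph.reassigned_chromatin_voxels == 1
        assert not (ph.compartment_mask("chromatin")
                    & ~ph.compartment_mask("nucleus")).any()

    def test_majority_stray_chromatin_is_channel_mixup(self):
        embryo, ab, p1, chrom = _tiny_masks()
        chrom[:] = False
        chrom[1, 1:5, 1:5] = True  # a slab entirely outside the nucleus
        with pytest.raises(ed.ChannelMixupError):
            ed.build_phantom(embryo, {"ab": ab, "p1": p1}, chrom,
                             pitch=(1.0, 1.0, 1.0))

    def test_empty_chromatin_is_valid(self):
        embryo, ab, p1, _ = _tiny_masks()
        ph = ed.build_phantom(embryo, {"ab": ab, "p1": p1}, None,
                              pitch=(1.0, 1.0, 1.0))
        assert ed.compartment_mass(ph, "chromatin") == 0.0

    def test_mismatched_lattices_rejected(self):
        embryo, ab, p1, chrom = _tiny_masks()
        with pytest.raises(ed.ValidationError):
            ed.build_phantom(embryo[:4], {"ab": ab}, chrom, pitch=(1,) * 3)


class TestCompartmentMass:
    def test_table_calibration_masses(self, default_masks):
        ph = ed.phantom_from_masks(default_masks)
        assert ed.compartment_mass(ph, "nucleus") == pytest.approx(2.1e-13, rel=0.03)
        assert ed.compartment_mass(ph, "chromatin") == pytest.approx(2.2e-14, rel=0.03)
        assert ed.compartment_mass(ph, "embryo") == pytest.approx(1.3e-11, rel=0.03)

    def test_mass_ordering_and_additivity(self, default_masks):
        ph = ed.phantom_from_masks(default_masks)
        m_e = ed.compartment_mass(ph, "embryo")
        m_n = ed.compartment_mass(ph, "nucleus")
        m_c = ed.compartment_mass(ph, "chromatin")
        assert m_e >= m_n >= m_c
        # embryo = non-nuclear embryo tissue + both nuclei (exact voxel sums)
        vox_kg = ph.voxel_volume_um3 * 1e-18 * 1000.0
        rest = int((ph.label_grid == EMBRYO_ONLY).sum()) * vox_kg
        m_p1 = ed.compartment_mass(ph, "p1_nucleus")
        assert m_e == pytest.approx(rest + m_n + m_p1, rel=1e-12)

    def test_zero_voxels_zero_mass(self):
        embryo, ab, p1, _ = _tiny_masks()
        ph = ed.build_phantom(embryo, {"ab": ab}, None, pitch=(0.5,) * 3)
        assert ed.compartment_mass(ph, "p1_nucleus") == 0.0

    def test_unknown_compartment_rejected(self, default_masks):
        ph = ed.phantom_from_masks(default_masks)
        with pytest.raises(ed.ValidationError):
            ed.compartment_mass(ph, "mitochondria")


class TestTextFormat:
    @pytest.fixture()
    def tiny_phantom(self):
        embryo, ab, p1, chrom = _tiny_masks()
        return ed.build_phantom(embryo, {"ab": ab, "p1": p1}, chrom,
                                pitch=(0.5, 0.5, 0.5), shift=(-1.0, 0.0, 2.5))

    def test_round_trip_identity(self, tiny_phantom, tmp_path):
        path = tmp_path / "p.txt"
        ed.write_phantom(tiny_phantom, path)
        back = ed.read_phantom(path)
        assert np.array_equal(back.label_grid, tiny_phantom.label_grid)
        assert back.voxel_pitch == tiny_phantom.voxel_pitch
        assert back.position_shift == tiny_phantom.position_shift

    def test_write_read_write_is_byte_identical(self, tiny_phantom, tmp_path):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        ed.write_phantom(tiny_phantom, p1)
        ed.write_phantom(ed.read_phantom(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_counts_match_compartments(self, tiny_phantom, tmp_path):
        path = tmp_path / "p.txt"
        ed.write_phantom(tiny_phantom, path)
        n_r, n_g, n_b = (int(x) for x in path.read_text().splitlines()[0].split())
        assert n_r == int(tiny_phantom.compartment_mask("embryo").sum())
        assert n_g == int(tiny_phantom.compartment_mask("nucleus").sum()
                          + tiny_phantom.compartment_mask("p1_nucleus").sum())
        assert n_b == int(tiny_phantom.compartment_mask("chromatin").sum())

    def test_record_count_mismatch_is_parse_error(self, tiny_phantom, tmp_path):
        path = tmp_path / "p.txt"
        ed.write_phantom(tiny_phantom, path)
        lines = path.read_text().splitlines()
        del lines[5]  # drop one record; header now disagrees
        bad = tmp_path / "bad.txt"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ed.PhantomFormatError, match="disagree"):
            ed.read_phantom(bad)

    def test_malformed_record_names_line(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("1 0 0\n0.5 0.5 0.5\n0 0 0\nR 0 0 zero 1 1.0\n")
        with pytest.raises(ed.PhantomFormatError, match="line 4"):
            ed.read_phantom(bad)

    def test_hand_written_two_voxel_file(self, tmp_path):
        text = ("2 1 0\n"
                "0.25 0.25 0.25\n"
                "-1 0 3.5\n"
                "R 0 0 0 1 1\n"
                "R 1 0 0 1 1\n"
                "G 1 0 0 1 1\n")
        f = tmp_path / "two.txt"
        f.write_text(text)
        ph = ed.read_phantom(f)
        assert ph.shape == (2, 1, 1)
        assert ph.label_grid[0, 0, 0] == EMBRYO_ONLY
        assert ph.label_grid[1, 0, 0] == NUCLEUS
        assert ph.voxel_pitch == (0.25, 0.25, 0.25)
        assert ph.position_shift == (-1.0, 0.0, 3.5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_random_phantom_round_trips(tmp_path_factory, data):
    """Any hierarchy-consistent random phantom survives write→read intact."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    shape = tuple(data.draw(st.integers(2, 6)) for _ in range(3))
    lab = rng.integers(0, 5, size=shape).astype(np.uint8)
    # ensure corner voxels are labelled so the bounding box is the grid
    lab[0, 0, 0] = EMBRYO_ONLY
    lab[-1, -1, -1] = P1_NUCLEUS
    ph = ed.VoxelPhantom(label_grid=lab, voxel_pitch=(0.5, 0.25, 1.0),
                         position_shift=(1.0, -2.0, 0.0))
    path = tmp_path_factory.mktemp("ph") / "p.txt"
    ed.write_phantom(ph, path)
    back = ed.read_phantom(path)
    assert np.array_equal(back.label_grid, ph.label_grid)
    assert back.voxel_pitch == ph.voxel_pitch
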