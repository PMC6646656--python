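"""Voxelized 3-compartment phantom and its text file format.

The phantom is a labelled voxel grid in liquid water: every voxel is
``outside``, ``embryo_only``, ``nucleus`` (the targeted AB nucleus),
``chromatin`` (⊆ AB nucleus) or ``p1_nucleus``. Voxel ``(i, j, k)`` has its
centre at ``position_shift + (i, j, k) * voxel_pitch`` (µm); the shift is
what centres the embryo in the simulated irradiation dish.

Text format (ASCII, whitespace-separated)::

    line 1:  nR nG nB          total voxels per colour channel
    line 2:  px py pz          voxel pitch, µm
    line 3:  sx sy sz          position shift, µm
    then one record per voxel:
             TAG ix iy iz MAT INTENSITY

where TAG is ``R`` (embryo), ``G`` (AB nucleus), ``P`` (P1 nucleus, counted
inside the green total nG), ``B`` (chromatin); indices are 0-based; MAT is
the material id (1 = liquid water); INTENSITY is the voxel's fluorescence
content. Records are canonically ordered R, G, P, B, each block in
lexicographic (ix, iy, iz) order, so write → read → write is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ChannelMixupError, PhantomFormatError, ValidationError

log = logging.getLogger(__name__)

# label encoding, ordered so that higher label = deeper in the hierarchy
OUTSIDE, EMBRYO_ONLY, NUCLEUS, CHROMATIN, P1_NUCLEUS = 0, 1, 2, 3, 4
LABEL_NAMES = {OUTSIDE: "outside", EMBRYO_ONLY: "embryo_only",
               NUCLEUS: "nucleus", CHROMATIN: "chromatin",
               P1_NUCLEUS: "p1_nucleus"}

WATER_MATERIAL_ID = 1
WATER_DENSITY_KG_M3 = 1000.0

COMPARTMENTS = ("chromatin", "nucleus", "embryo", "p1_nucleus")

_NUM_FMT = "%.6g"


@dataclass
class VoxelPhantom:
    """Labelled voxel grid with water material and fluorescence content."""

    label_grid: np.ndarray                       # uint8, [ix, iy, iz]
    voxel_pitch: tuple[float, float, float]      # µm
    position_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density_kg_m3: float = WATER_DENSITY_KG_M3
    intensity: np.ndarray | None = None          # same shape, float
    reassigned_chromatin_voxels: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid, np.uint8)
        if self.intensity is not None \
                and self.intensity.shape != self.label_grid.shape:
            raise ValidationError("intensity grid shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_pitch))

    def compartment_mask(self, compartment: str) -> np.ndarray:
        lab = self.label_grid
        if compartment == "chromatin":
            return lab == CHROMATIN
        if compartment == "nucleus":
            return (lab == NUCLEUS) | (lab == CHROMATIN)
        if compartment == "p1_nucleus":
            return lab == P1_NUCLEUS
        if compartment == "embryo":
            return lab != OUTSIDE
        raise ValidationError(
            f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")

    def voxel_centers_um(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.position_shift[axis] + np.arange(n) * self.voxel_pitch[axis]

    def world_to_index(self, point_um) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point_um, float)
                       - np.asarray(self.position_shift))
                      / np.asarray(self.voxel_pitch)).astype(int)
        return tuple(int(i) for i in idx)


def build_phantom(
    embryo_mask: np.ndarray,
    nucleus_masks: dict[str, np.ndarray] | np.ndarray,
    chromatin_mask: np.ndarray | None,
    pitch: tuple[float, float, float],
    shift: tuple[float, float, float] | None = None,
    intensity: np.ndarray | None = None,
) -> VoxelPhantom:
    """Assemble compartment masks into a labelled phantom.

    ``nucleus_masks`` is the AB nucleus mask, or a mapping with keys
    ``"ab"`` and optionally ``"p1"``. The label hierarchy is enforced:
    chromatin voxels outside the nucleus are absorbed into the nucleus and
    counted (logged); if more than half the chromatin lies outside the
    nucleus a :class:`ChannelMixupError` is raised (channels swapped).
    The grid is cropped to the embryo bounding box and the shift adjusted,
    which makes the text format round trip exactly.
    """
    embryo = np.asarray(embryo_mask, bool)
    if isinstance(nucleus_masks, dict):
        ab = np.asarray(nucleus_masks["ab"], bool)
        p1 = np.asarray(nucleus_masks.get("p1"), bool) \
            if nucleus_masks.get("p1") is not None else np.zeros_like(ab)
    else:
        ab = np.asarray(nucleus_masks, bool)
        p1 = np.zeros_like(ab)
    chrom = (np.asarray(chromatin_mask, bool) if chromatin_mask is not None
             else np.zeros_like(ab))
    shapes = {embryo.shape, ab.shape, p1.shape, chrom.shape}
    if len(shapes) > 1:
        raise ValidationError("compartment masks must share one lattice")
    if (ab & p1).any():
        raise ValidationError("AB and P1 nucleus masks overlap")

    n_chrom = int(chrom.sum())
    outside_nuc = int((chrom & ~ab).sum())
    if n_chrom and outside_nuc > 0.5 * n_chrom:
        raise ChannelMixupError(
            f"{outside_nuc}/{n_chrom} chromatin voxels fall outside the "
            "nucleus — colour channels are probably swapped")
    if outside_nuc:
        log.warning("reassigning %d chromatin voxels into the nucleus",
                    outside_nuc)
        ab = ab | chrom
    # nuclei are embryo tissue by definition
    embryo = embryo | ab | p1

    lab = np.zeros(embryo.shape, np.uint8)
    lab[embryo] = EMBRYO_ONLY
    lab[p1] = P1_NUCLEUS
    lab[ab] = NUCLEUS
    lab[chrom] = CHROMATIN

    # crop to the labelled bounding box; adjust the shift so world
    # coordinates are unchanged
    if shift is None:
        shift = (0.0, 0.0, 0.0)
    nz = np.nonzero(lab)
    if len(nz[0]) == 0:
        raise ValidationError("phantom has no labelled voxels")
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    lab = lab[sl]
    inten = None
    if intensity is not None:
        inten = np.asarray(intensity, float)[sl]
    shift = tuple(float(s + a * p) for s, a, p in zip(shift, lo, pitch))

    return VoxelPhantom(label_grid=lab, voxel_pitch=tuple(pitch),
                        position_shift=shift, intensity=inten,
                        reassigned_chromatin_voxels=outside_nuc)


def compartment_mass(phantom: VoxelPhantom, compartment: str) -> float:
    """Compartment mass in kg: voxel count × voxel volume × water density."""
    n = int(phantom.compartment_mask(compartment).sum())
    voxel_m3 = phantom.voxel_volume_um3 * 1e-18
    return n * voxel_m3 * phantom.density_kg_m3


# ---------------------------------------------------------------------------
# text format

_CHANNELS = (("R", "embryo"), ("G", "nucleus"), ("P", "p1_nucleus"),
             ("B", "chromatin"))


def write_phantom(phantom: VoxelPhantom, path) -> None:
    """Write the phantom in the ASCII voxel-list format (see module docs)."""
    lines = []
    counts = {}
    blocks = []
    for tag, comp in _CHANNELS:
        mask = phantom.compartment_mask(comp)
        idx = np.argwhere(mask)  # argwhere is already lexicographic
        counts[tag] = len(idx)
        if len(idx) == 0:
            continue
        if phantom.intensity is not None:
            inten = phantom.intensity[mask.nonzero()]
        else:
            inten = np.ones(len(idx))
        blocks.append((tag, idx, inten))
    n_red = counts["R"]
    n_green = counts["G"] + counts["P"]
    n_blue = counts["B"]
    lines.append(f"{n_red} {n_green} {n_blue}")
    lines.append(" ".join(_NUM_FMT % p for p in phantom.voxel_pitch))
    lines.append(" ".join(_NUM_FMT % s for s in phantom.position_shift))
    for tag, idx, inten in blocks:
        mat = WATER_MATERIAL_ID
        for (i, j, k), v in zip(idx, inten):
            lines.append(f"{tag} {i} {j} {k} {mat} {_NUM_FMT % v}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_triple(line: str, lineno: int, kind: str, cast):
    parts = line.split()
    if len(parts) != 3:
        raise PhantomFormatError(
            f"line {lineno}: expected three {kind} values, got {line!r}")
    try:
        return tuple(cast(p) for p in parts)
    except ValueError:
        raise PhantomFormatError(
            f"line {lineno}: could not parse {kind} values from {line!r}"
        ) from None


def read_phantom(path) -> VoxelPhantom:
    """Read a phantom text file; inverse of :func:`write_phantom`.

    Raises :class:`PhantomFormatError` (naming the offending line) on
    malformed records or a record count that disagrees with the header.
    """
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise PhantomFormatError("file has fewer than 3 header lines")
    n_red, n_green, n_blue = _parse_triple(text[0], 1, "integer", int)
    pitch = _parse_triple(text[1], 2, "decimal", float)
    shift = _parse_triple(text[2], 3, "decimal", float)

    records: dict[str, list] = {"R": [], "G": [], "P": [], "B": []}
    intens: dict[str, list] = {"R": [], "G": [], "P": [], "B": []}
    for lineno, line in enumerate(text[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PhantomFormatError(
                f"line {lineno}: expected 'TAG ix iy iz mat intensity', "
                f"got {line!r}")
        tag = parts[0]
        if tag not in records:
            raise PhantomFormatError(f"line {lineno}: unknown channel tag {tag!r}")
        try:
            ijk = tuple(int(p) for p in parts[1:4])
            int(parts[4])
            inten = float(parts[5])
        except ValueError:
            raise PhantomFormatError(
                f"line {lineno}: malformed record {line!r}") from None
        if any(i < 0 for i in ijk):
            raise PhantomFormatError(
                f"line {lineno}: negative voxel index in {line!r}")
        records[tag].append(ijk)
        intens[tag].append(inten)

    got = {"red": len(records["R"]),
           "green": len(records["G"]) + len(records["P"]),
           "blue": len(records["B"])}
    want = {"red": n_red, "green": n_green, "blue": n_blue}
    if got != want:
        raise PhantomFormatError(
            f"record counts {got} disagree with header counts {want}")

    all_idx = np.array([ijk for tag in records for ijk in records[tag]], int)
    if len(all_idx) == 0:
        raise PhantomFormatError("file contains no voxel records")
    shape = tuple(int(m) + 1 for m in all_idx.max(axis=0))
    lab = np.zeros(shape, np.uint8)
    inten_grid = np.zeros(shape, float)
    for tag, label in (("R", EMBRYO_ONLY), ("G", NUCLEUS), ("P", P1_NUCLEUS),
                       ("B", CHROMATIN)):
        if records[tag]:
            idx = tuple(np.array(records[tag], int).T)
            lab[idx] = label
            inten_grid[idx] = intens[tag]
    return VoxelPhantom(label_grid=lab, voxel_pitch=pitch,
                        position_shift=shift, intensity=inten_grid)
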