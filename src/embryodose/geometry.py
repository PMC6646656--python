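"""Parametric 2-cell embryo geometries and ground-truth voxel masks.

The embryo envelope is an axis-aligned ellipsoid whose default semiaxes
(25 × 15.5 × 8.0 µm) give a volume of ≈ 1.3 × 10⁴ µm³ (1.3 × 10⁻¹¹ kg at
water density) and a beam chord of ≈ 15.5 µm through the AB target point.
The AB nucleus is a spheroid: lateral diameter 7.4 µm by default (a
212 µm³ ≈ 2.1 × 10⁻¹³ kg sphere), with an independently settable extent
along the beam (z) axis so that populations with a prescribed distribution
of traversed nuclear chords can be sampled. The P1 nucleus sits ≥ 10 µm
away along the anteroposterior (x) axis and never sees the beam.

Chromatin (default 22 µm³ ≈ 2.2 × 10⁻¹⁴ kg) is arranged inside the AB
nucleus according to a :class:`~embryodose.states.CondensationState`; its
voxelized volume is matched across states by bisecting the free blob radius.

All masks live on one voxel lattice: arrays indexed ``[ix, iy, iz]``,
world coordinate of voxel ``(i, j, k)`` centre = ``origin + index * pitch``,
with the embryo centred at the world origin and the beam travelling along
+z.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError
from .states import CONDENSATION_STATES, CondensationState, get_state

_GRID_PAD_UM = 0.45  # margin of water around the embryo envelope

#: Nominal nuclear mass the defaults are calibrated to (kg at water density).
NOMINAL_NUCLEUS_MASS_KG = 2.1e-13


@dataclass(frozen=True)
class EmbryoGeometrySpec:
    """Complete parametric description of one 2-cell embryo.

    All lengths in µm; triples are (x, y, z) with z the beam axis.

    Parameters
    ----------
    embryo_semiaxes : ellipsoid semiaxes of the embryo envelope.
    ab_nucleus_center : centre of the targeted AB nucleus.
    ab_nucleus_diameter : lateral (x, y) diameter of the AB nucleus;
        biologically 6.5–8.5 µm.
    ab_nucleus_z_diameter : extent along the beam axis; ``None`` means a
        sphere. This equals the central beam chord through the nucleus.
    p1_nucleus_center, p1_nucleus_diameter : the non-irradiated P1 nucleus.
    chromatin_state : condensation state label or object.
    chromatin_volume : total chromatin volume, µm³.
    voxel_pitch : lattice pitch per axis, µm.
    seed : controls the (seeded) azimuthal placement of peripheral blobs.
    """

    embryo_semiaxes: tuple[float, float, float] = (25.0, 15.5, 8.0)
    ab_nucleus_center: tuple[float, float, float] = (-6.5, 0.0, 0.0)
    ab_nucleus_diameter: float = 7.4
    ab_nucleus_z_diameter: float | None = None
    p1_nucleus_center: tuple[float, float, float] = (6.0, 0.0, 0.0)
    p1_nucleus_diameter: float = 6.5
    chromatin_state: str | CondensationState = "prophase_early"
    chromatin_volume: float = 22.0
    voxel_pitch: tuple[float, float, float] = (0.2, 0.2, 0.2)
    seed: int = 0

    def with_(self, **kw) -> "EmbryoGeometrySpec":
        return dataclasses.replace(self, **kw)

    @property
    def ab_semiaxes(self) -> tuple[float, float, float]:
        r = self.ab_nucleus_diameter / 2.0
        cz = (self.ab_nucleus_z_diameter or self.ab_nucleus_diameter) / 2.0
        return (r, r, cz)

    @property
    def ab_nucleus_volume(self) -> float:
        a, b, c = self.ab_semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def embryo_volume(self) -> float:
        a, b, c = self.embryo_semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c

    def validate(self) -> None:
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValidationError("voxel_pitch must be positive")
        if self.ab_nucleus_diameter <= 0 or self.p1_nucleus_diameter <= 0:
            raise ValidationError("nucleus diameters must be positive")
        if self.chromatin_volume < 0:
            raise ValidationError("chromatin_volume must be non-negative")
        if self.chromatin_volume >= self.ab_nucleus_volume:
            raise ValidationError(
                f"chromatin_volume {self.chromatin_volume} µm³ must be smaller "
                f"than the AB nucleus volume {self.ab_nucleus_volume:.1f} µm³"
            )
        get_state(self.chromatin_state)
        for name, center, semi in (
            ("AB", self.ab_nucleus_center, self.ab_semiaxes),
            ("P1", self.p1_nucleus_center,
             (self.p1_nucleus_diameter / 2,) * 3),
        ):
            # conservative containment bound for a spheroid in the envelope
            s = sum(((abs(c) + r) / a) ** 2
                    for c, r, a in zip(center, semi, self.embryo_semiaxes))
            if s > 1.0:
                raise GeometryError(
                    f"{name} nucleus (centre {center}, semiaxes {semi}) does not "
                    f"fit inside the embryo envelope {self.embryo_semiaxes}"
                )
        d = np.linalg.norm(np.subtract(self.ab_nucleus_center,
                                       self.p1_nucleus_center))
        touch = self.ab_nucleus_diameter / 2 + self.p1_nucleus_diameter / 2
        if d <= touch:
            raise GeometryError(
                f"AB and P1 nuclei overlap (centre distance {d:.2f} µm)"
            )


@dataclass
class GroundTruthMasks:
    """Boolean compartment masks on a common voxel lattice.

    Subset relations hold by construction:
    ``chromatin ⊆ AB nucleus``, ``AB ∪ P1 nucleus ⊆ embryo``, AB ∩ P1 = ∅.
    """

    embryo_mask: np.ndarray
    ab_nucleus_mask: np.ndarray
    p1_nucleus_mask: np.ndarray
    chromatin_mask: np.ndarray
    voxel_pitch: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.embryo_mask.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_pitch))

    def volume_um3(self, which: str) -> float:
        mask = getattr(self, f"{which}_mask")
        return int(mask.sum()) * self.voxel_volume_um3

    def world_to_index(self, point_um) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point_um, float) - np.asarray(self.origin))
                      / np.asarray(self.voxel_pitch)).astype(int)
        return tuple(int(i) for i in idx)

    def ab_central_chord_um(self, target_um=None) -> float:
        """Beam-axis chord through the AB nucleus at the target (x, y)."""
        if target_um is None:
            ix, iy, _ = self.world_to_index(self._ab_center)
        else:
            ix, iy, _ = self.world_to_index(target_um)
        return float(self.ab_nucleus_mask[ix, iy, :].sum()) * self.voxel_pitch[2]

    # populated by make_embryo_geometry for convenience
    _ab_center: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _axes_coords(spec: EmbryoGeometrySpec):
    """Symmetric world-coordinate axes covering the embryo plus margin."""
    axes = []
    origin = []
    for semi, pitch in zip(spec.embryo_semiaxes, spec.voxel_pitch):
        half = semi + _GRID_PAD_UM
        n = int(np.ceil(2 * half / pitch))
        if n % 2 == 0:
            n += 1  # odd count -> a voxel centre exactly at 0
        coords = (np.arange(n) - (n - 1) / 2) * pitch
        axes.append(coords)
        origin.append(coords[0])
    return axes, tuple(origin)


def _ellipsoid_mask(axes, center, semiaxes) -> np.ndarray:
    x, y, z = axes
    dx = (x - center[0]) / semiaxes[0]
    dy = (y - center[1]) / semiaxes[1]
    dz = (z - center[2]) / semiaxes[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2) <= 1.0


def _bisect_radius(count_fn, target: int, r_max: float) -> float:
    """Largest-resolution bisection of a monotone voxel-count function.

    Returns the radius whose count is closest to ``target`` among the two
    bracketing values (counts jump in lattice-symmetric shells, so an exact
    hit is not always possible).
    """
    lo, hi = 0.0, r_max
    if count_fn(hi) < target:
        raise GeometryError(
            "chromatin volume cannot be reached inside the nucleus "
            "(blobs would have to extend beyond it)"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count_fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi if abs(count_fn(hi) - target) <= abs(count_fn(lo) - target) else lo


def _chromatin_mask(spec: EmbryoGeometrySpec, axes, ab_mask: np.ndarray,
                    state: CondensationState) -> np.ndarray:
    """Voxelize the state's chromatin arrangement inside the AB nucleus."""
    pitch = spec.voxel_pitch
    vox = float(np.prod(pitch))
    target = int(round(spec.chromatin_volume / vox))
    mask = np.zeros_like(ab_mask)
    if target == 0:
        return mask
    cx, cy, cz = spec.ab_nucleus_center
    x, y, z = axes

    # work inside the AB-nucleus bounding box only
    ii = np.nonzero(ab_mask.any(axis=(1, 2)))[0]
    jj = np.nonzero(ab_mask.any(axis=(0, 2)))[0]
    kk = np.nonzero(ab_mask.any(axis=(0, 1)))[0]
    sl = (slice(ii[0], ii[-1] + 1), slice(jj[0], jj[-1] + 1),
          slice(kk[0], kk[-1] + 1))
    xs, ys, zs = x[sl[0]], y[sl[1]], z[sl[2]]
    nuc = ab_mask[sl]
    sub = np.zeros_like(nuc)

    rng = np.random.default_rng(spec.seed)

    if state.spheroids:
        centers = [(cx + dx, cy + dy, cz + dz) for dx, dy, dz in state.spheroids]

        def count(r: float) -> int:
            m = np.zeros_like(nuc)
            for c in centers:
                m |= _ellipsoid_mask((xs, ys, zs), c, (r, r, r))
            return int((m & nuc).sum())

        # spheroids may clip against a thin nucleus (a metaphase plate in a
        # flattened nucleus becomes a lens); the intersection keeps the
        # count monotone in r, so bisection still lands on the volume
        r_max = max(spec.ab_semiaxes)
        r = _bisect_radius(count, target, r_max)
        for c in centers:
            sub |= _ellipsoid_mask((xs, ys, zs), c, (r, r, r))
        sub &= nuc
    else:
        # on-axis plate: the n_layers voxel layers nearest the nucleus centre
        k_c = int(np.argmin(np.abs(zs - cz)))
        half = state.plate_layers // 2
        if state.plate_layers % 2:
            layers = range(k_c - half, k_c + half + 1)
        else:
            layers = range(k_c - half + 1, k_c + half + 1)
        lateral = ((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
                   <= state.plate_radius_um ** 2)
        plate = np.zeros_like(nuc)
        for k in layers:
            if 0 <= k < nuc.shape[2]:
                plate[:, :, k] = lateral
        plate &= nuc
        sub |= plate
        remaining = target - int(plate.sum())
        if remaining > 0 and state.ring_blobs > 0:
            phase = rng.uniform(0, 2 * np.pi)
            angles = phase + 2 * np.pi * np.arange(state.ring_blobs) / state.ring_blobs
            centers = [(cx + state.ring_radius_um * np.cos(a),
                        cy + state.ring_radius_um * np.sin(a), cz)
                       for a in angles]

            def count(r: float) -> int:
                m = plate.copy()
                for c in centers:
                    m |= _ellipsoid_mask((xs, ys, zs), c, (r, r, r))
                return int((m & nuc).sum())

            r_max = max(spec.ab_semiaxes)
            r = _bisect_radius(count, target, r_max)
            for c in centers:
                sub |= _ellipsoid_mask((xs, ys, zs), c, (r, r, r))
            sub &= nuc
        elif remaining < 0:
            # plate alone overshoots (tiny chromatin volumes): trim the plate
            # laterally by bisection instead
            def count(r: float) -> int:
                lat = ((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
                       <= r ** 2)
                m = np.zeros_like(nuc)
                for k in layers:
                    if 0 <= k < nuc.shape[2]:
                        m[:, :, k] = lat
                return int((m & nuc).sum())

            r = _bisect_radius(count, target, state.plate_radius_um)
            sub[:] = False
            lat = ((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r ** 2)
            for k in layers:
                if 0 <= k < nuc.shape[2]:
                    sub[:, :, k] = lat
            sub &= nuc

    mask[sl] = sub
    return mask


def make_embryo_geometry(spec: EmbryoGeometrySpec) -> GroundTruthMasks:
    """Voxelize one embryo specification into ground-truth masks.

    Deterministic for a fixed ``spec.seed``. Raises
    :class:`~embryodose.errors.GeometryError` if a nucleus does not fit the
    envelope and :class:`~embryodose.errors.ValidationError` for impossible
    chromatin volumes.
    """
    spec.validate()
    axes, origin = _axes_coords(spec)
    embryo = _ellipsoid_mask(axes, (0.0, 0.0, 0.0), spec.embryo_semiaxes)
    ab = _ellipsoid_mask(axes, spec.ab_nucleus_center, spec.ab_semiaxes)
    p1 = _ellipsoid_mask(axes, spec.p1_nucleus_center,
                         (spec.p1_nucleus_diameter / 2,) * 3)
    ab &= embryo
    p1 &= embryo
    if (ab & p1).any():
        raise GeometryError("AB and P1 nucleus masks overlap after voxelization")
    chromatin = _chromatin_mask(spec, axes, ab, get_state(spec.chromatin_state))
    masks = GroundTruthMasks(
        embryo_mask=embryo, ab_nucleus_mask=ab, p1_nucleus_mask=p1,
        chromatin_mask=chromatin, voxel_pitch=spec.voxel_pitch, origin=origin,
    )
    masks._ab_center = spec.ab_nucleus_center
    return masks


def sample_population(
    n: int,
    mean_chord: float = 6.0,
    chord_variation: float = 1.5,
    state_mix: dict[str, float] | None = None,
    seed: int = 0,
    base_spec: EmbryoGeometrySpec | None = None,
) -> list[EmbryoGeometrySpec]:
    """Sample a population of embryo specs with prescribed nuclear chords.

    The beam-axis central chord through each AB nucleus is drawn from a
    uniform distribution with mean ``mean_chord`` and standard deviation
    ``chord_variation`` (i.e. uniform on ``mean ± √3·variation``), so the
    chord CV is ``variation / mean``; condensation states are drawn from
    ``state_mix`` (mapping state label → weight; default equal weights).

    With the defaults (6, 1.5 µm) this emulates a population of fixed
    embryos whose traversed nuclear thickness averages 6 µm with a spread
    (SD) of 1.5 µm — a 25% cell-to-cell fluctuation.
    """
    if n < 1:
        raise ValidationError("population size must be ≥ 1")
    if not (0 <= chord_variation * np.sqrt(3) < mean_chord):
        raise ValidationError(
            "require 0 ≤ √3·chord_variation < mean_chord (chords must stay "
            "positive)")
    if state_mix is None:
        state_mix = {s: 1.0 for s in CONDENSATION_STATES}
    if not state_mix:
        raise ValidationError("state_mix must not be empty")
    for s in state_mix:
        get_state(s)
    base = base_spec or EmbryoGeometrySpec()
    rng = np.random.default_rng(seed)
    labels = list(state_mix)
    weights = np.array([state_mix[s] for s in labels], float)
    weights = weights / weights.sum()
    half = np.sqrt(3.0) * chord_variation
    chords = rng.uniform(mean_chord - half, mean_chord + half, size=n)
    states = rng.choice(labels, size=n, p=weights)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        base.with_(ab_nucleus_z_diameter=float(chords[i]),
                   chromatin_state=str(states[i]), seed=int(child_seeds[i]))
        for i in range(n)
    ]
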