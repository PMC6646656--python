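"""Confocal-like 3-channel image stacks rendered from ground-truth masks.

Emulates the staining used on fixed 2-cell embryos: red (phalloidin /
actin) encodes the embryo envelope, blue (Hoechst) the chromatin, and green
the nuclear ROI. Noise is additive Gaussian on a constant background —
no optical PSF, photobleaching or refractive effects are simulated, so any
threshold between background and foreground recovers the masks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ValidationError
from .geometry import GroundTruthMasks

log = logging.getLogger(__name__)

CHANNEL_NAMES = ("red", "green", "blue")


@dataclass(frozen=True)
class IntensityLevels:
    """Mean channel intensities (arbitrary units, uint16 range)."""

    background: float = 600.0
    red: float = 1600.0
    green: float = 1600.0
    blue: float = 1600.0

    def foreground(self, channel: str) -> float:
        return getattr(self, channel)


@dataclass
class ImageStack:
    """3-channel 3D intensity stack on one voxel lattice.

    ``channels[name]`` is a float array indexed ``[ix, iy, iz]``; all
    channels share shape and pitch. ``origin`` is the world coordinate of
    voxel (0, 0, 0)'s centre, in µm.
    """

    channels: dict[str, np.ndarray]
    voxel_pitch: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValidationError("all channels must share one shape")
        for name, c in self.channels.items():
            if np.any(c < 0):
                raise ValidationError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def save_tiff(self, path, channel: str | None = None) -> None:
        """Write one channel (or all, interleaved as CZYX) as TIFF.

        Voxel pitch and world origin travel in the shaped metadata so a
        stack survives a save/load round trip geometrically intact.
        """
        meta = {"pitch_um": list(self.voxel_pitch),
                "origin_um": [float(o) for o in self.origin]}
        if channel is not None:
            data = self.channels[channel].transpose(2, 1, 0)
            tifffile.imwrite(path, data.astype(np.float32),
                             metadata={"axes": "ZYX", "channel": channel,
                                       **meta})
        else:
            data = np.stack([self.channels[c].transpose(2, 1, 0)
                             for c in CHANNEL_NAMES])
            tifffile.imwrite(path, data.astype(np.float32),
                             metadata={"axes": "CZYX",
                                       "channels": list(CHANNEL_NAMES),
                                       **meta})

    @classmethod
    def load_tiff(cls, path, voxel_pitch=None, origin=None) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = (tf.shaped_metadata or [{}])[0]
        if data.ndim != 4 or data.shape[0] != 3:
            raise ValidationError(
                f"expected a CZYX stack with 3 channels, got shape {data.shape}"
            )
        if voxel_pitch is None:
            voxel_pitch = meta.get("pitch_um", (0.2, 0.2, 0.2))
        if origin is None:
            origin = meta.get("origin_um", (0.0, 0.0, 0.0))
        channels = {name: np.asarray(data[i], float).transpose(2, 1, 0)
                    for i, name in enumerate(CHANNEL_NAMES)}
        return cls(channels=channels, voxel_pitch=tuple(voxel_pitch),
                   origin=tuple(float(o) for o in origin))


def render_stack(
    masks: GroundTruthMasks,
    intensity_levels: IntensityLevels | None = None,
    snr: float = 10.0,
    seed: int = 0,
    green_includes_p1: bool = True,
) -> ImageStack:
    """Render a noisy 3-channel stack from ground-truth masks.

    The noise standard deviation per channel is
    ``(foreground - background) / snr``; ``snr <= 1`` is allowed but logs a
    warning (segmentation is then unreliable). Seeded and reproducible.
    """
    levels = intensity_levels or IntensityLevels()
    for ch in CHANNEL_NAMES:
        if levels.foreground(ch) <= levels.background:
            raise ValidationError(
                f"{ch} foreground level must exceed the background mean"
            )
    if snr <= 1:
        warnings.warn(f"requested SNR {snr} <= 1: channels will be dominated "
                      "by noise", stacklevel=2)
        log.warning("rendering stack at SNR %.3g <= 1", snr)

    green_mask = masks.ab_nucleus_mask
    if green_includes_p1:
        green_mask = green_mask | masks.p1_nucleus_mask
    planes = {"red": masks.embryo_mask, "green": green_mask,
              "blue": masks.chromatin_mask}
    rng = np.random.default_rng(seed)
    channels = {}
    for name in CHANNEL_NAMES:
        fg = levels.foreground(name)
        img = np.where(planes[name], fg, levels.background).astype(float)
        if snr > 0 and np.isfinite(snr):
            sd = (fg - levels.background) / snr
            if sd > 0:
                img = img + rng.normal(0.0, sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)
    return ImageStack(channels=channels, voxel_pitch=masks.voxel_pitch,
                      origin=masks.origin,
                      metadata={"snr": snr, "seed": seed,
                                "green_includes_p1": green_includes_p1})
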