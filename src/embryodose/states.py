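"""Chromatin condensation states of the dividing AB blastomere.

Five mitotic stages are modelled, ordered by how much of a nucleus-targeted
beam's path intersects chromatin. The total chromatin volume (default
22 µm³) is identical across states; only its spatial arrangement changes:

* diffuse states (interphase and the two prophase stages) place most of the
  chromatin as a ring of off-axis blobs near the nuclear periphery, with a
  thin on-axis plate — 1–2 voxel layers thick, of state-specific lateral
  radius — representing the portion of the diffuse chromatin that the beam
  column actually traverses;
* ``metaphase`` condenses everything into one compact spheroid centred on
  the beam axis (the metaphase plate seen end-on);
* ``anaphase`` splits it into two spheroids separating along the spindle
  (anteroposterior) axis, partially off the beam.

The plate radii were fixed once from the closed-form LET × path estimate so
that the chromatin energy share rises from a few percent (diffuse) to
roughly half (metaphase) of the nuclear energy, the behaviour observed for
targeted proton microbeams across mitosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STATE_LABELS = (
    "interphase_decondensed",
    "prophase_early",
    "prophase_late",
    "anaphase",
    "metaphase",
)

# Ordering index from least to most condensed on the beam axis.
STATE_ORDER = {label: i for i, label in enumerate(STATE_LABELS)}


@dataclass(frozen=True)
class CondensationState:
    """Parametric chromatin arrangement for one mitotic stage.

    Attributes
    ----------
    label : state name, one of :data:`STATE_LABELS`.
    plate_radius_um : lateral radius of the on-axis chromatin plate
        (0 disables the plate).
    plate_layers : plate thickness in voxel layers along the beam axis.
    ring_blobs : number of off-axis peripheral blobs carrying the chromatin
        volume not in the plate.
    ring_radius_um : lateral distance of blob centres from the nucleus centre.
    spheroids : explicit list of (dx, dy, dz) spheroid centre offsets (µm)
        that receive equal shares of the *whole* chromatin volume; used by
        metaphase/anaphase instead of plate + ring.
    """

    label: str
    plate_radius_um: float = 0.0
    plate_layers: int = 1
    ring_blobs: int = 0
    ring_radius_um: float = 2.9
    spheroids: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(
                f"unknown condensation state {self.label!r}; expected one of {STATE_LABELS}"
            )


CONDENSATION_STATES: dict[str, CondensationState] = {
    "interphase_decondensed": CondensationState(
        "interphase_decondensed", plate_radius_um=1.05, plate_layers=1, ring_blobs=6
    ),
    "prophase_early": CondensationState(
        "prophase_early", plate_radius_um=1.80, plate_layers=1, ring_blobs=6
    ),
    "prophase_late": CondensationState(
        "prophase_late", plate_radius_um=1.12, plate_layers=2, ring_blobs=5
    ),
    "anaphase": CondensationState(
        "anaphase", spheroids=((-1.6, 0.0, 0.0), (1.6, 0.0, 0.0))
    ),
    "metaphase": CondensationState("metaphase", spheroids=((0.0, 0.0, 0.0),)),
}

PROPHASE_STATES = ("prophase_early", "prophase_late")


def get_state(state: str | CondensationState) -> CondensationState:
    if isinstance(state, CondensationState):
        return state
    try:
        return CONDENSATION_STATES[state]
    except KeyError:
        raise ValueError(
            f"unknown condensation state {state!r}; expected one of {STATE_LABELS}"
        ) from None
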