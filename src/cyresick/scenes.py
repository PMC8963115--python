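"""Scene attribute registry and single-factor contrast definitions.

The stimulus set is a flight-navigation VR corpus of 52 scenes designed for
isolated-factor analysis of cybersickness: every attribute of interest
(rotation axis, translation axis, speed, acceleration, field of view, frame
reference, duration, controllability) is varied in at least one matched scene
pair while all other attributes are held fixed.  Scenes fall into three
categories: CCU (controllable urban), CUA (uncontrollable astrospace) and
CUU (uncontrollable urban).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Scene",
    "ContrastSpec",
    "load_scene_table",
    "packaged_scene_table",
    "category_duration",
    "contrast_registry",
    "validate_contrast",
    "COMPONENTS",
    "ROTATION_COMPONENTS",
    "TRANSLATION_COMPONENTS",
]

COMPONENTS = ("ry", "rr", "rp", "tf", "tb", "tl", "tu", "td")
ROTATION_COMPONENTS = frozenset({"ry", "rr", "rp"})
TRANSLATION_COMPONENTS = frozenset({"tf", "tb", "tl", "tu", "td"})

BACKGROUNDS = ("urban", "astrospace")
MOVEMENT_CLASSES = ("simple", "complex")
TRANSLATION_SPEEDS = ("none", "moderate_4mps", "fast_9.2mps")
CATEGORIES = ("CCU", "CUA", "CUU")
FOV_CHOICES = (30, 45, 90)

SPEED_MPS = {"none": 0.0, "moderate_4mps": 4.0, "fast_9.2mps": 9.2}


@dataclass(frozen=True)
class Scene:
    """One scene's full attribute vector.

    ``components`` uses the standard shorthand: ry/rr/rp are yaw, roll and
    pitch camera rotations; tf/tb/tl/tu/td are forward, backward, lateral,
    upward and downward translations.  ``acceleration_rate`` is the terminal
    translation speed as a fraction of the initial speed (1.60 means the
    speed ramps up to 160%); ``None`` means constant speed.
    ``duration_measured`` marks durations that are mean measured experience
    times (controllable scenes end when the user reaches the endpoint) rather
    than nominal clip lengths.
    """

    scene_id: str
    background: str
    movement_class: str
    components: frozenset = field(default_factory=frozenset)
    acceleration_rate: float | None = None
    translation_speed: str = "none"
    fov_deg: int = 90
    frame_reference: bool = False
    duration_s: float = 13.0
    duration_measured: bool = False
    controllable: bool = False
    category: str = "CUU"

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"{self.scene_id}: unknown background {self.background!r}")
        if self.movement_class not in MOVEMENT_CLASSES:
            raise ValueError(
                f"{self.scene_id}: unknown movement class {self.movement_class!r}"
            )
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"{self.scene_id}: unknown components {sorted(unknown)}")
        if self.movement_class == "simple" and len(self.components) != 1:
            raise ValueError(
                f"{self.scene_id}: simple movement requires exactly one component"
            )
        if self.translation_speed not in TRANSLATION_SPEEDS:
            raise ValueError(
                f"{self.scene_id}: unknown translation speed {self.translation_speed!r}"
            )
        if self.components and self.components <= ROTATION_COMPONENTS:
            if self.translation_speed != "none":
                raise ValueError(
                    f"{self.scene_id}: rotation-only scene must have no translation speed"
                )
        if self.fov_deg not in FOV_CHOICES:
            raise ValueError(f"{self.scene_id}: fov_deg must be one of {FOV_CHOICES}")
        if self.duration_s <= 0:
            raise ValueError(f"{self.scene_id}: duration must be positive")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.scene_id}: unknown category {self.category!r}")
        if self.controllable and self.category != "CCU":
            raise ValueError(f"{self.scene_id}: controllable scenes are category CCU")
        if self.category == "CUA" and self.background != "astrospace":
            raise ValueError(f"{self.scene_id}: CUA scenes have astrospace background")
        if self.acceleration_rate is not None and self.acceleration_rate <= 1.0:
            raise ValueError(
                f"{self.scene_id}: acceleration terminal rate must exceed 1.0"
            )

    @property
    def acceleration(self) -> bool:
        return self.acceleration_rate is not None

    @property
    def translation_speed_mps(self) -> float:
        return SPEED_MPS[self.translation_speed]


# Attributes a contrast can name as its varied factor, and how each maps onto
# Scene fields for the mechanical matched-pair check.
_FACTORS = (
    "rotation_axis",
    "translation_axis",
    "vertical_translation",
    "fov",
    "acceleration",
    "speed",
    "frame_reference",
    "duration",
    "controllability",
)

_FACTOR_FIELDS = {
    "rotation_axis": ("components",),
    "translation_axis": ("components",),
    "vertical_translation": ("components",),
    "fov": ("fov_deg",),
    "acceleration": ("acceleration_rate",),
    "speed": ("translation_speed",),
    "frame_reference": ("frame_reference",),
    "duration": ("duration_s",),
    "controllability": ("controllable", "category", "duration_s", "duration_measured"),
}

_COMPARABLE_FIELDS = (
    "movement_class",
    "components",
    "acceleration_rate",
    "translation_speed",
    "fov_deg",
    "frame_reference",
    "duration_s",
    "controllable",
)


@dataclass(frozen=True)
class ContrastSpec:
    """A single-factor comparison between two matched scene sets.

    ``condition_a`` and ``condition_b`` list scene ids; scenes are paired
    positionally (same index in both lists shares its background twin), and
    each cross-condition pair must differ only in the named factor.
    """

    factor: str
    condition_a: tuple
    condition_b: tuple
    label_a: str = ""
    label_b: str = ""

    def __post_init__(self) -> None:
        if self.factor not in _FACTORS:
            raise ValueError(f"unknown contrast factor {self.factor!r}")
        if len(self.condition_a) != len(self.condition_b):
            raise ValueError("conditions must pair scenes one-to-one")


def _parse_bool(token: str) -> bool:
    t = str(token).strip().lower()
    if t in {"yes", "true", "1"}:
        return True
    if t in {"no", "false", "0", ""}:
        return False
    raise ValueError(f"cannot parse boolean token {token!r}")


def load_scene_table(path) -> list:
    """Load a scene attribute table (CSV) into validated :class:`Scene` records.

    Raises ``ValueError`` on duplicate scene ids, unknown enum tokens or any
    violated scene invariant, reporting the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "scene_id", "background", "movement_class", "components",
        "acceleration_rate", "translation_speed", "fov_deg",
        "frame_reference", "duration_s", "controllable", "category",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scene table is missing columns: {sorted(missing)}")
    scenes = []
    seen = set()
    for i, row in df.iterrows():
        sid = row["scene_id"].strip()
        if sid in seen:
            raise ValueError(f"duplicate scene_id {sid!r} at row {i}")
        seen.add(sid)
        try:
            comps = frozenset(
                c for c in (t.strip() for t in row["components"].split(";")) if c
            )
            accel = row["acceleration_rate"].strip()
            scene = Scene(
                scene_id=sid,
                background=row["background"].strip(),
                movement_class=row["movement_class"].strip(),
                components=comps,
                acceleration_rate=float(accel) if accel else None,
                translation_speed=row["translation_speed"].strip(),
                fov_deg=int(row["fov_deg"]),
                frame_reference=_parse_bool(row["frame_reference"]),
                duration_s=float(row["duration_s"]),
                duration_measured=_parse_bool(row.get("duration_measured", "no")),
                controllable=_parse_bool(row["controllable"]),
                category=row["category"].strip(),
            )
        except ValueError as exc:
            raise ValueError(f"scene table row {i} ({sid}): {exc}") from exc
        scenes.append(scene)
    return scenes


def packaged_scene_table() -> list:
    """The full 52-scene table shipped with the package."""
    ref = importlib.resources.files("cyresick.data") / "scenes.csv"
    with importlib.resources.as_file(ref) as path:
        return load_scene_table(path)


def category_duration(scenes, category: str) -> float:
    """Total stimulus duration (seconds) of one scene category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return float(sum(s.duration_s for s in scenes if s.category == category))


def contrast_registry() -> list:
    """All nine single-factor contrasts defined on the packaged scene set.

    Each contrast lists the scene ids whose attributes are identical except
    for the factor under test; background twins (astrospace/urban) appear at
    matching positions so paired tests can average them per participant.
    """
    return [
        ContrastSpec("rotation_axis", ("S102", "S202"), ("S101", "S201"),
                     "roll", "yaw"),
        ContrastSpec("rotation_axis", ("S102", "S202"), ("S103", "S203"),
                     "roll", "pitch"),
        ContrastSpec("rotation_axis", ("S103", "S203"), ("S101", "S201"),
                     "pitch", "yaw"),
        ContrastSpec("translation_axis", ("S105", "S205"), ("S104", "S204"),
                     "backward", "forward"),
        ContrastSpec("translation_axis", ("S105", "S205"), ("S106", "S206"),
                     "backward", "lateral"),
        ContrastSpec("vertical_translation", ("S107", "S207"), ("S104", "S204"),
                     "upward", "forward"),
        ContrastSpec("vertical_translation", ("S108", "S208"), ("S104", "S204"),
                     "downward", "forward"),
        ContrastSpec("fov", ("S114", "S214"), ("S110", "S210"),
                     "middle_45", "large_90"),
        ContrastSpec("fov", ("S115", "S215"), ("S110", "S210"),
                     "small_30", "large_90"),
        ContrastSpec("fov", ("S115", "S215"), ("S114", "S214"),
                     "small_30", "middle_45"),
        ContrastSpec("acceleration", ("S116", "S216"), ("S110", "S210"),
                     "accelerating", "constant"),
        ContrastSpec("speed", ("S112", "S212"), ("S110", "S210"),
                     "fast_9.2mps", "moderate_4mps"),
        ContrastSpec("frame_reference", ("S118", "S218"), ("S117", "S217"),
                     "with_reference", "without_reference"),
        ContrastSpec("duration", ("S224",), ("S210",),
                     "long_24s", "short_13s"),
        ContrastSpec("controllability",
                     ("S001", "S002", "S007", "S008"),
                     ("S210", "S211", "S224", "S225"),
                     "controllable", "uncontrollable"),
    ]


def validate_contrast(spec: ContrastSpec, scenes) -> None:
    """Check that every cross-condition scene pair differs only in the factor.

    Attributes mapped to the contrast's factor are required to differ in at
    least one pair; all other comparable attributes must match within every
    pair.  Raises ``ValueError`` with the offending pair and attribute.
    """
    by_id = {s.scene_id: s for s in scenes}
    varied = set(_FACTOR_FIELDS[spec.factor])
    factor_differs = False
    for sid_a, sid_b in zip(spec.condition_a, spec.condition_b):
        try:
            a, b = by_id[sid_a], by_id[sid_b]
        except KeyError as exc:
            raise ValueError(f"contrast references unknown scene {exc}") from exc
        for attr in _COMPARABLE_FIELDS:
            va, vb = getattr(a, attr), getattr(b, attr)
            if attr in varied:
                if va != vb:
                    factor_differs = True
            elif va != vb:
                raise ValueError(
                    f"{spec.factor}: pair ({sid_a}, {sid_b}) differs in "
                    f"uncontrolled attribute {attr!r} ({va!r} vs {vb!r})"
                )
    if not factor_differs:
        raise ValueError(f"{spec.factor}: no pair differs in the named factor")
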