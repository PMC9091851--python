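"""Core domain types and the arithmetic of radial porosity profiles (RPPs).

An RPP is a four-point trajectory of primary cortical porosity measured in
four radial quadrants (a = innermost/oldest, d = outermost/youngest) of a
measurement sector spanning the posthatching cortex of a limb-bone
mid-diaphyseal cross-section.  Per-quadrant porosity is the percentage of the
quadrant occupied by primary vascular spaces, with secondarily remodelled bone
and the lamellar boundary layers (outer circumferential layer, OCL; endosteal
lamellar layer, EL) subtracted from the sampled area.  Sector profiles are
averaged quadrant-wise into a mean RPP per bone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ELEMENTS",
    "DEV_STRATEGIES",
    "QUADRANTS",
    "SpecimenMetadata",
    "QuadrantMeasure",
    "SectorProfile",
    "RPPTrajectory",
    "LayerThickness",
    "quadrant_porosity",
    "mean_rpp",
    "is_analysable",
    "center_rpp",
    "relative_layer_thickness",
    "estimate_age_from_mass",
    "formann_min_sample",
]

#: Controlled vocabulary of measurable limb elements.
ELEMENTS = (
    "humerus",
    "ulna",
    "radius",
    "carpometacarpus",
    "alula",
    "femur",
    "tibiotarsus",
    "tarsometatarsus",
)

DEV_STRATEGIES = ("altricial", "precocial", "unknown")

#: Quadrant labels ordered innermost -> outermost.
QUADRANTS = ("a", "b", "c", "d")

#: Intercept and slope of the hatchling body-mass/age line for hoatzins
#: (mass in grams = MASS_INTERCEPT + MASS_SLOPE * age in days posthatching).
MASS_INTERCEPT = 9.61
MASS_SLOPE = 5.63


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenMetadata:
    """Identity and biology of one sampled bone.

    Parameters
    ----------
    specimen_id : str
        Individual animal identifier (several elements may share it).
    taxon : str
        Taxon name, free text.
    element : str
        Skeletal element, one of :data:`ELEMENTS`.
    age_dph : float or None
        Age in days posthatching; ``None`` when unknown.
    body_mass_g : float or None
        Fresh body mass in grams; ``None`` when unknown.
    dev_strategy : str
        Developmental strategy of the element ("altricial", "precocial",
        "unknown").  In ducks, wing elements develop altricially and leg
        elements precocially.
    """

    specimen_id: str
    taxon: str = ""
    element: str = "humerus"
    age_dph: float | None = None
    body_mass_g: float | None = None
    dev_strategy: str = "unknown"

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise InvalidInputError(
                f"element {self.element!r} not in controlled vocabulary {ELEMENTS}"
            )
        if self.dev_strategy not in DEV_STRATEGIES:
            raise InvalidInputError(
                f"dev_strategy {self.dev_strategy!r} not in {DEV_STRATEGIES}"
            )
        if self.age_dph is not None and self.age_dph < 0:
            raise InvalidInputError("age_dph must be non-negative")
        if self.body_mass_g is not None and self.body_mass_g <= 0:
            raise InvalidInputError("body_mass_g must be positive")

    @property
    def element_id(self) -> str:
        return f"{self.specimen_id}:{self.element}"


@dataclass(frozen=True)
class QuadrantMeasure:
    """Raw areas and derived porosity for one quadrant of one sector.

    ``excluded_area`` collects remodelled (secondary) bone, OCL and EL within
    the quadrant; it is subtracted from the quadrant area before the porosity
    percentage is formed.  ``porosity`` is ``None`` when the quadrant is
    dominated by exclusions (fully/mostly remodelled).
    """

    quadrant_index: str
    quadrant_area: float
    vascular_area: float
    excluded_area: float = 0.0
    porosity: float | None = None
    exclusion_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.quadrant_index not in QUADRANTS:
            raise InvalidInputError(f"quadrant_index must be one of {QUADRANTS}")
        if self.quadrant_area < 0 or self.vascular_area < 0 or self.excluded_area < 0:
            raise InvalidInputError("areas must be non-negative")
        if self.porosity is not None and not (0.0 <= self.porosity <= 100.0):
            raise InvalidInputError("porosity must lie in [0, 100]")


@dataclass(frozen=True)
class SectorProfile:
    """One sector's four-point porosity profile, inner -> outer.

    ``values`` has exactly four entries (quadrants a..d); ``nan`` encodes a
    missing quadrant (e.g. obliterated by secondary remodelling).
    """

    sector_index: int
    values: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.values) != 4:
            raise InvalidInputError("a sector profile has exactly 4 quadrant values")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class RPPTrajectory:
    """Sector-averaged radial porosity profile of one bone.

    ``values`` are the quadrant means over however many sectors each quadrant
    was measurable in; ``nan`` marks quadrants missing in every sector.
    ``centred`` trajectories hold deviations from the trajectory's own mean
    porosity instead of raw percentages.
    """

    metadata: SpecimenMetadata
    values: tuple[float, float, float, float]
    n_sectors: int = 1
    centred: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != 4:
            raise InvalidInputError("an RPP has exactly 4 points")
        if self.n_sectors < 1:
            raise InvalidInputError("n_sectors must be >= 1")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def element_id(self) -> str:
        return self.metadata.element_id

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.as_array())))

    @property
    def is_complete(self) -> bool:
        return self.n_present == 4


@dataclass(frozen=True)
class LayerThickness:
    """Relative areal thickness of a lamellar boundary layer (OCL or EL)."""

    layer: str
    relative_area_percent: float

    def __post_init__(self) -> None:
        if self.layer not in ("OCL", "EL"):
            raise InvalidInputError("layer must be 'OCL' or 'EL'")
        if not (0.0 <= self.relative_area_percent <= 100.0):
            raise InvalidInputError("relative_area_percent must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def quadrant_porosity(
    vascular_area: float, quadrant_area: float, excluded_area: float = 0.0
) -> float | None:
    """Porosity percentage of a quadrant after exclusion subtraction.

    Returns ``100 * vascular_area / (quadrant_area - excluded_area)``, i.e.
    the fraction of the *primary* sampled area occupied by vascular spaces.
    Secondary bone, OCL and EL area within the quadrant are passed as
    ``excluded_area`` and removed from the denominator.

    Returns ``None`` (missing) when exclusions consume the entire quadrant —
    the quadrant is fully remodelled and carries no primary porosity signal.
    """
    if quadrant_area <= 0:
        raise InvalidInputError("quadrant_area must be positive")
    if vascular_area < 0 or excluded_area < 0:
        raise InvalidInputError("areas must be non-negative")
    if excluded_area >= quadrant_area:
        return None
    sampled = quadrant_area - excluded_area
    if vascular_area > sampled * (1 + 1e-9):
        raise InvalidInputError(
            "vascular_area exceeds sampled (quadrant - excluded) area"
        )
    return 100.0 * vascular_area / sampled


def mean_rpp(
    profiles: Sequence[SectorProfile],
    metadata: SpecimenMetadata | None = None,
) -> RPPTrajectory:
    """Quadrant-wise mean of sector profiles: the bone's mean RPP.

    Each entry k is the mean of quadrant k over the sectors where it is
    non-missing (available-case averaging); an entry is missing only when the
    quadrant is missing in every sector.
    """
    if not profiles:
        raise InvalidInputError("mean_rpp needs at least one sector profile")
    mat = np.array([p.values for p in profiles], dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column -> nan
        means = np.nanmean(mat, axis=0)
    meta = metadata or SpecimenMetadata(specimen_id="unknown")
    return RPPTrajectory(
        metadata=meta, values=tuple(means), n_sectors=len(profiles), centred=False
    )


def is_analysable(traj: RPPTrajectory) -> bool:
    """Whether a trajectory has enough points for numeric analysis.

    A minimum of two of the four quadrant points must be present.
    """
    return traj.n_present >= 2


def center_rpp(traj: RPPTrajectory) -> RPPTrajectory:
    """Centre a trajectory on its own mean porosity.

    Subtracts the mean of the non-missing entries from every non-missing
    entry, so only the *shape* of the profile remains; missing entries stay
    missing.  Idempotent (centring a centred trajectory is a no-op).
    """
    if not is_analysable(traj):
        raise InvalidInputError("cannot centre a trajectory with < 2 points")
    arr = traj.as_array()
    mu = np.nanmean(arr)
    return replace(traj, values=tuple(arr - mu), centred=True)


def relative_layer_thickness(layer_area: float, total_cortex_area: float) -> float:
    """Area percentage a lamellar layer occupies of the total cortex area."""
    if total_cortex_area <= 0:
        raise InvalidInputError("total_cortex_area must be positive")
    if layer_area < 0 or layer_area > total_cortex_area * (1 + 1e-9):
        raise InvalidInputError("layer_area must lie in [0, total_cortex_area]")
    return 100.0 * min(layer_area, total_cortex_area) / total_cortex_area


def estimate_age_from_mass(body_mass_g: float) -> float:
    """Age in days posthatching from fresh body mass (hoatzin chicks).

    Inverts the linear hatchling growth relation
    ``mass = 9.61 + 5.63 * age`` fitted for hoatzins, so
    ``age = (mass - 9.61) / 5.63``.  Masses at or below the hatchling
    intercept have no positive age and are rejected.
    """
    if body_mass_g <= MASS_INTERCEPT:
        raise InvalidInputError(
            f"body mass {body_mass_g} g is at or below the hatchling "
            f"intercept ({MASS_INTERCEPT} g); age undefined"
        )
    return (body_mass_g - MASS_INTERCEPT) / MASS_SLOPE


def formann_min_sample(n_parameters: int) -> int:
    """Minimum sample size 2**d for a d-parameter multivariate clustering.

    Rule of thumb for latent-class style analyses: with d trajectory points
    (here, quadrants) per observation the sample should contain at least
    2**d elements.
    """
    if n_parameters < 1:
        raise InvalidInputError("n_parameters must be >= 1")
    return 2**n_parameters
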