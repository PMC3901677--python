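"""Default parameter sets for cat beta-cell-like mosaics.

These defaults define the reference study conditions used throughout the
package: a ~1 mm² retinal field with ON/OFF beta-cell densities typical of
mid-peripheral cat retina, soft homotypic repulsion producing semiregular
mosaics, a hard ON–OFF soma core, a dipole distance in the middle of the
sensible 60–100 µm range, and a cat-like cortical column spacing of 1 mm
seen through a magnification of 1.7 mm cortex per mm retina.  See
docs/methods.md for how each number was chosen.
"""
from __future__ import annotations

from .core import InteractionParams, MPIPPConfig, PairRepulsion
from .opm import cortex_to_retina

__all__ = [
    "CAT_BETA_INTERACTIONS",
    "M623_DENSITY_ON",
    "M623_DENSITY_OFF",
    "M623_WINDOW",
    "DIPOLE_DISTANCE",
    "CAT_MAGNIFICATION",
    "CAT_COLUMN_SPACING_CORTEX_MM",
    "OPM_PIXEL_SIZE",
    "cat_column_spacing_retina_um",
    "mosaic_counts",
    "default_config",
]

#: soft repulsion within a polarity and hard soma core between polarities (µm)
CAT_BETA_INTERACTIONS = InteractionParams(
    on_on=PairRepulsion(delta=30.0, phi=40.0, alpha=2.5),
    off_off=PairRepulsion(delta=30.0, phi=40.0, alpha=2.5),
    on_off=PairRepulsion(delta=15.0),
)

#: reference ON/OFF beta-cell densities, cells per mm²
M623_DENSITY_ON = 72.0
M623_DENSITY_OFF = 76.0

#: reference ~1 mm field (µm)
M623_WINDOW = (0.0, 1000.0, 0.0, 1000.0)

#: dipole / modulation distance d (µm)
DIPOLE_DISTANCE = 80.0

#: cortical magnification M, mm cortex per mm retina
CAT_MAGNIFICATION = 1.7

#: typical cat orientation-column spacing on the cortex, mm
CAT_COLUMN_SPACING_CORTEX_MM = 1.0

#: default OPM grid resolution, µm per pixel (retinal)
OPM_PIXEL_SIZE = 10.0


def cat_column_spacing_retina_um(magnification: float = CAT_MAGNIFICATION) -> float:
    """Column spacing Λ in retinal µm implied by the linear retinotopy."""
    return 1000.0 * cortex_to_retina(CAT_COLUMN_SPACING_CORTEX_MM, magnification)


def mosaic_counts(area_mm2: float = 1.0) -> tuple[int, int]:
    """(n_on, n_off) at the reference densities for a given area."""
    return (round(M623_DENSITY_ON * area_mm2), round(M623_DENSITY_OFF * area_mm2))


def default_config(beta: float = 0.0, seed: int = 0, n_sweeps: int = 20,
                   magnification: float = CAT_MAGNIFICATION) -> MPIPPConfig:
    """An :class:`MPIPPConfig` at the reference dipole distance."""
    return MPIPPConfig(beta=beta, d_mod=DIPOLE_DISTANCE, n_sweeps=n_sweeps,
                       magnification=magnification, seed=seed)
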