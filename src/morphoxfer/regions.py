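"""Region registry and parcel geometry.

The analysis operates on 82 brain regions: 68 cortical thickness parcels
(34 Desikan-Killiany gyral parcels per hemisphere, FreeSurfer naming) and
14 subcortical volume parcels (7 Harvard-Oxford structures per hemisphere).
Cortical parcels additionally carry a unit-sphere centroid used by the
spin-permutation test; subcortical structures have no spherical embedding
and are excluded from spatial rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DESIKAN_KILLIANY_PARCELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

HARVARD_OXFORD_STRUCTURES: tuple[str, ...] = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
)


@dataclass(frozen=True)
class Region:
    """One atlas parcel: identity, tissue class, and hemisphere."""

    name: str
    atlas: str  # "Desikan-Killiany" | "Harvard-Oxford"
    tissue: str  # "cortical" | "subcortical"
    hemisphere: str  # "L" | "R"


class RegionRegistry:
    """Ordered collection of the 82 analysis regions.

    The registry fixes canonical column names and ordering for every
    morphometry table in the package: cortical columns are FreeSurfer-style
    ``lh_<parcel>_thickness`` / ``rh_<parcel>_thickness`` (mm), subcortical
    columns are ``Left-<Structure>_volume`` / ``Right-<Structure>_volume``
    (mm^3).
    """

    def __init__(self, regions: Sequence[Region]):
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        n_cort = sum(r.tissue == "cortical" for r in regions)
        n_sub = sum(r.tissue == "subcortical" for r in regions)
        if n_cort != 68 or n_sub != 14:
            raise ValueError(
                f"registry requires 68 cortical + 14 subcortical regions, "
                f"got {n_cort} + {n_sub}"
            )
        self._regions = tuple(regions)
        self._index = {r.name: i for i, r in enumerate(self._regions)}

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> Region:
        return self._regions[self._index[name]]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self._regions]

    @property
    def cortical(self) -> list[Region]:
        return [r for r in self._regions if r.tissue == "cortical"]

    @property
    def subcortical(self) -> list[Region]:
        return [r for r in self._regions if r.tissue == "subcortical"]

    def tissue_of(self, name: str) -> str:
        return self[name].tissue


def default_registry() -> RegionRegistry:
    """The canonical 68 + 14 region registry in fixed order (cortical first)."""
    regions: list[Region] = []
    for hemi, prefix in (("L", "lh"), ("R", "rh")):
        for parcel in DESIKAN_KILLIANY_PARCELS:
            regions.append(
                Region(
                    name=f"{prefix}_{parcel}_thickness",
                    atlas="Desikan-Killiany",
                    tissue="cortical",
                    hemisphere=hemi,
                )
            )
    for hemi, prefix in (("L", "Left"), ("R", "Right")):
        for struct in HARVARD_OXFORD_STRUCTURES:
            regions.append(
                Region(
                    name=f"{prefix}-{struct}_volume",
                    atlas="Harvard-Oxford",
                    tissue="subcortical",
                    hemisphere=hemi,
                )
            )
    return RegionRegistry(regions)


@dataclass(frozen=True)
class ParcelGeometry:
    """Unit-sphere centroids for the cortical parcels.

    ``centroids`` maps cortical region name -> (x, y, z) on the unit sphere.
    Left/right homologues mirror in x (x < 0 on the left). Subcortical
    regions carry no centroid and are flagged non-spherical.
    """

    centroids: dict[str, np.ndarray]
    non_spherical: tuple[str, ...]

    def array_for(self, names: Iterable[str]) -> np.ndarray:
        rows = []
        for n in names:
            if n not in self.centroids:
                raise KeyError(f"no centroid for region {n!r}")
            rows.append(self.centroids[n])
        return np.asarray(rows, float)


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def generate_parcel_geometry(registry: RegionRegistry) -> ParcelGeometry:
    """Deterministic synthetic centroids for the cortical parcels.

    Left-hemisphere centroids are laid out on a golden-angle spiral over the
    x < 0 half of the unit sphere (a low-discrepancy layout, so nearest
    neighbours stay well separated); right-hemisphere centroids are the
    x-mirrored images. These are synthetic stand-ins for surface-derived
    parcel centroids; only relative geometry matters for the spin test.
    """
    left = [r for r in registry.cortical if r.hemisphere == "L"]
    right = [r for r in registry.cortical if r.hemisphere == "R"]
    if len(left) != len(right):
        raise ValueError("hemispheres must have equal parcel counts")
    n = len(left)
    centroids: dict[str, np.ndarray] = {}
    for k, (lreg, rreg) in enumerate(zip(left, right)):
        # polar angle about the -x axis; keep strictly inside the hemisphere
        cos_alpha = 1.0 - 0.92 * (k + 0.5) / n
        sin_alpha = np.sqrt(1.0 - cos_alpha**2)
        phi = _GOLDEN_ANGLE * k
        p = np.array(
            [-cos_alpha, sin_alpha * np.cos(phi), sin_alpha * np.sin(phi)]
        )
        centroids[lreg.name] = p
        centroids[rreg.name] = p * np.array([-1.0, 1.0, 1.0])
    return ParcelGeometry(
        centroids=centroids,
        non_spherical=tuple(r.name for r in registry.subcortical),
    )
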