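"""Cortical atlas fixture: 360 parcels (180 per hemisphere), MD membership,
and a canonical resting-state network assignment.

The analysis operates on a multimodal parcellation with 180 areas per
hemisphere.  Multiple-demand (MD) areas carry their published labels
(i6-8, p9-46v, a9-46v, 8BM, SCEF, AVI, IP1, IP2, ...); the remaining
parcels get systematic placeholder names.  The network assignment is a
synthetic fixture shaped like the Cole-Anticevic network partition
(CAB-NP) as it intersects the MD system: all 10 core MD areas sit in the
fronto-parietal network (FPN), penumbra areas scatter over FPN, the
cingulo-opercular network (CON), the dorsal attention network (DAN) and
the default-mode network (DMN), and the FPN additionally contains eight
non-MD areas.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Atlas",
    "default_atlas",
    "CORE_FULL_AREAS",
    "CORE_PARTIAL_AREAS",
    "CORE_AREAS",
    "PENUMBRA_AREAS",
    "EXTENDED_MD_AREAS",
    "CORE_PARTIAL_CONTRASTS",
    "SUBCORTICAL_STRUCTURES",
    "N_AREAS_PER_HEMI",
]

N_AREAS_PER_HEMI = 180

# Core MD: strongest activation, significantly above the extended-set mean.
# Seven areas exceed the mean in all three contrasts; three more in two of
# three (IFJp: relational & math; 8C and PFm: working memory & relational).
CORE_FULL_AREAS = ("i6-8", "p9-46v", "a9-46v", "8BM", "AVI", "IP2", "IP1")
CORE_PARTIAL_AREAS = ("IFJp", "8C", "PFm")
CORE_AREAS = CORE_FULL_AREAS + CORE_PARTIAL_AREAS

# Contrast indices (into the default WM / relational / math order) in which
# each partial-core area is planted above the extended-set mean.
CORE_PARTIAL_CONTRASTS = {"IFJp": (1, 2), "8C": (0, 1), "PFm": (0, 1)}

# Penumbra: the remaining extended-MD areas (significant in the three-way
# conjunction but not above the extended-set mean).
PENUMBRA_AREAS = (
    "a47r", "p47r", "a10p", "p10p", "11l", "6r", "s6-8",
    "AIP", "LIPd", "MIP", "PGs", "POS2", "TE1m", "TE1p",
    "FOP5", "a32pr", "FOP4",
)

EXTENDED_MD_AREAS = CORE_AREAS + PENUMBRA_AREAS  # 27 areas

# SCEF is not itself an extended-MD area (activation ramps up only over its
# anterior segments) but is carried in the FC analyses as penumbra.
SCEF = "SCEF"

_NETWORKS_MD = {
    # core: all in FPN
    **{a: "FPN" for a in CORE_AREAS},
    # penumbra: 10 FPN, 4 CON, 3 DAN, 1 DMN
    **{a: "FPN" for a in ("a47r", "p47r", "a10p", "p10p", "11l",
                          "s6-8", "POS2", "TE1m", "TE1p", "FOP4")},
    **{a: "CON" for a in (SCEF, "FOP5", "6r", "a32pr")},
    **{a: "DAN" for a in ("AIP", "LIPd", "MIP")},
    "PGs": "DMN",
}

_FILLER_NETWORKS = (
    "VIS1", "VIS2", "SMN", "AUD", "LAN", "DMN", "DAN", "CON", "PMM", "VMM", "ORA",
)

# FreeSurfer-style segmentation labels for 19 subcortical/cerebellar
# structures (9 bilateral pairs plus the brain stem).
_BILATERAL = (
    "Caudate", "Putamen", "Pallidum", "Thalamus", "Cerebellum",
    "Hippocampus", "Amygdala", "VentralDC", "Accumbens",
)
SUBCORTICAL_STRUCTURES = tuple(
    f"{side}_{s}" for s in _BILATERAL for side in ("Left", "Right")
) + ("Brain-Stem",)


@dataclass(frozen=True)
class Atlas:
    """Area names, per-area network labels, and parcel-level expansions."""

    area_names: tuple          # 180 names, shared by both hemispheres
    networks: dict             # area name -> network label

    @property
    def n_areas(self) -> int:
        return len(self.area_names)

    @property
    def parcel_ids(self) -> tuple:
        """360 parcel names: all left-hemisphere areas then all right."""
        return tuple(f"L_{a}" for a in self.area_names) + tuple(
            f"R_{a}" for a in self.area_names
        )

    @property
    def parcel_hemispheres(self) -> tuple:
        return ("L",) * self.n_areas + ("R",) * self.n_areas

    @property
    def parcel_area_names(self) -> tuple:
        return self.area_names + self.area_names

    def md_class(self, area: str, scef_as_penumbra: bool = True) -> str:
        """'core', 'penumbra' or 'nonMD' for an area name.

        In the FC analyses the 8BM/SCEF composite is unpacked: 8BM counts
        as core and SCEF as penumbra (``scef_as_penumbra=True``).
        """
        if area in CORE_AREAS:
            return "core"
        if area in PENUMBRA_AREAS:
            return "penumbra"
        if area == SCEF and scef_as_penumbra:
            return "penumbra"
        return "nonMD"

    def parcel_partition(self, scef_as_penumbra: bool = True) -> dict:
        """Parcel id -> {'core','penumbra','nonMD'} for all 360 parcels."""
        return {
            pid: self.md_class(a, scef_as_penumbra)
            for pid, a in zip(self.parcel_ids, self.parcel_area_names)
        }


def default_atlas() -> Atlas:
    """Build the packaged 180-area atlas fixture.

    Named MD areas come first (in a fixed order), then SCEF, then eight
    non-MD FPN areas, then systematically named filler parcels cycled over
    the remaining networks.
    """
    names = list(EXTENDED_MD_AREAS) + [SCEF]
    networks = dict(_NETWORKS_MD)
    for i in range(8):  # non-MD members of the FPN
        name = f"FPNx{i + 1}"
        names.append(name)
        networks[name] = "FPN"
    i = 0
    while len(names) < N_AREAS_PER_HEMI:
        name = f"P{i + 1:03d}"
        names.append(name)
        networks[name] = _FILLER_NETWORKS[i % len(_FILLER_NETWORKS)]
        i += 1
    return Atlas(area_names=tuple(names), networks=networks)
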