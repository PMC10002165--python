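"""Region-of-interest registry.

The default registry covers the 33 forebrain ROIs quantified at the
topographical level of the striatum (coronal sections, Bregma +1.68 to
+1.44 in the Paxinos atlas), plus the genu of the corpus callosum (gcc)
as the white-matter reference channel.  The gcc carries no specific
hybridization signal and is used only to normalize the analysis ROIs;
it is therefore *not* part of the analysis ROI list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["ROIRegistry", "default_registry", "DEFAULT_ROIS", "REFERENCE_ROI"]

REFERENCE_ROI = "gcc"

#: (abbreviation, full name) for the 33 analysis ROIs, in canonical order.
DEFAULT_ROIS: tuple[tuple[str, str], ...] = (
    ("LSV", "Lateral septal nucleus, ventral"),
    ("Tu", "Olfactory tubercle"),
    ("LSD", "Lateral septal nucleus, dorsal"),
    ("LSI", "Lateral septal nucleus, intermediate"),
    ("Icj", "Islands of Calleja"),
    ("VP", "Ventral pallidum"),
    ("Shi", "Septohippocampal nucleus"),
    ("MS", "Medial septum"),
    ("VDB", "Nucleus of the vertical limb of the diagonal band"),
    ("IG", "Indusium griseum"),
    ("S1dz", "Somatosensory 1, dysgranular zone"),
    ("AIV", "Agranular insular area, ventral"),
    ("S1ULp", "Upper lip of the primary somatosensory cortex"),
    ("GI", "Granular insular cortex"),
    ("DI", "Dysgranular insular cortex"),
    ("AcSh", "Accumbens nucleus, shell"),
    ("Pir", "Piriform cortex"),
    ("AID", "Agranular insular area, dorsal"),
    ("LSS", "Lateral stripe of striatum"),
    ("Cg2", "Cingulate cortex, area 2"),
    ("CPDL", "Dorsolateral caudate putamen"),
    ("CPVL", "Ventrolateral caudate putamen"),
    ("CPVM", "Ventromedial caudate putamen"),
    ("Cg1", "Cingulate cortex, area 1"),
    ("M2", "Supplementary motor cortex"),
    ("CPDM", "Dorsomedial caudate putamen"),
    ("Den", "Dorsal endopiriform nucleus"),
    ("M1", "Primary motor cortex"),
    ("S1Fl", "Somatosensory 1, forelimb region"),
    ("AcCo", "Accumbens nucleus, core"),
    ("Cl", "Claustrum"),
    ("S1j", "Somatosensory 1, jaw region"),
    ("S1jO", "Primary somatosensory cortex, jaw region, oral surface"),
)


@dataclass(frozen=True)
class ROIRegistry:
    """Ordered set of analysis ROIs plus a reference (normalization) region.

    Parameters
    ----------
    entries
        Ordered ``(abbreviation, full_name)`` pairs for the analysis ROIs.
    reference_roi
        Abbreviation of the reference channel (default ``"gcc"``).  The
        reference is never an analysis ROI.
    """

    entries: tuple[tuple[str, str], ...]
    reference_roi: str = REFERENCE_ROI
    reference_name: str = "Genu of the corpus callosum"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("registry needs at least one analysis ROI")
        abbrs = [a for a, _ in self.entries]
        if len(set(abbrs)) != len(abbrs):
            dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
            raise ValueError(f"duplicate ROI abbreviations: {dupes}")
        if self.reference_roi in abbrs:
            raise ValueError(
                f"reference ROI {self.reference_roi!r} must not be an analysis ROI"
            )

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.entries)

    @property
    def n_rois(self) -> int:
        return len(self.entries)

    def __contains__(self, abbr: str) -> bool:
        return abbr in self.abbreviations

    def index(self, abbr: str) -> int:
        return self.abbreviations.index(abbr)

    def full_name(self, abbr: str) -> str:
        for a, name in self.entries:
            if a == abbr:
                return name
        raise KeyError(abbr)

    def subset(self, abbrs: Iterable[str]) -> "ROIRegistry":
        """Registry restricted to ``abbrs`` (kept in registry order)."""
        keep = set(abbrs)
        missing = keep - set(self.abbreviations)
        if missing:
            raise KeyError(f"unknown ROIs: {sorted(missing)}")
        return ROIRegistry(
            entries=tuple((a, n) for a, n in self.entries if a in keep),
            reference_roi=self.reference_roi,
            reference_name=self.reference_name,
        )


def default_registry() -> ROIRegistry:
    """The canonical 33-ROI registry with gcc as reference."""
    return ROIRegistry(entries=DEFAULT_ROIS)
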