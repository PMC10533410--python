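"""Phenotype registry: the fixed vocabulary of cell phenotypes and markers.

The analysis assumes a two-compartment phenotype taxonomy — epithelial
(cancer) cell phenotypes versus tumour-microenvironment (TME) phenotypes —
with a coarser three-way category map (epithelial / immune / stromal) used
for composition summaries. The default registry mirrors a 17 epithelial +
20 TME panel typical of high-plex imaging studies of breast cancer; any
registry sizes are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EPITHELIAL = "epithelial"
TME = "TME"

DEFAULT_EPITHELIAL = (
    "CKhi_Epi",
    "CKlo_GATA3_Epi",
    "CKlo_AR_Epi",
    "Basal_Epi",
    "CK8_18_Epi",
    "MHCI_II_hi_Epi",
    "MHCI_hi_Epi",
    "CD15_Epi",
    "HLA_DR_Epi",
    "CA9_Epi",
    "Vim_Epi",
    "pHH3_Epi",
    "CKmed_Epi",
    "GATA3hi_Epi",
    "CD56_NE_Epi",
    "Apoptotic_Epi",
    "CKlo_Epi",
)

DEFAULT_TME = (
    "CD8_T",
    "CD8_GZMB_T",
    "CD8_TCF1_T",
    "CD8_PD1_Tex",
    "CD4_T",
    "CD4_TCF1_T",
    "Treg",
    "CD20_B",
    "CD79a_Plasma",
    "NK",
    "M2_Mac",
    "DC",
    "PDL1_APC",
    "PDL1_IDO_APC",
    "Neutrophil",
    "Mast",
    "Fibroblast",
    "Myofibroblast",
    "PDPN_Stromal",
    "Endothelial",
)

DEFAULT_STROMAL = ("Fibroblast", "Myofibroblast", "PDPN_Stromal", "Endothelial")

DEFAULT_T_CELLS = (
    "CD8_T",
    "CD8_GZMB_T",
    "CD8_TCF1_T",
    "CD8_PD1_Tex",
    "CD4_T",
    "CD4_TCF1_T",
    "Treg",
)

DEFAULT_MARKERS = (
    "panCK",
    "CK5",
    "CD8a",
    "CD4",
    "CD20",
    "Ki67",
    "TOX",
    "PD1",
    "GZMB",
    "OX40",
    "ICOS",
    "Vimentin",
    "Calponin",
    "Carboplatin",
)

#: markers whose expression distinguishes activated T cells
DEFAULT_ACTIVATION_MARKERS = ("TOX", "PD1", "GZMB", "OX40", "ICOS")

DEFAULT_CYTOKERATINS = ("panCK", "CK5")


@dataclass(frozen=True)
class PhenotypeRegistry:
    """Fixed phenotype/marker vocabulary shared by all pipeline stages."""

    epithelial: tuple[str, ...] = DEFAULT_EPITHELIAL
    tme: tuple[str, ...] = DEFAULT_TME
    stromal: tuple[str, ...] = DEFAULT_STROMAL
    t_cells: tuple[str, ...] = DEFAULT_T_CELLS
    markers: tuple[str, ...] = DEFAULT_MARKERS
    activation_markers: tuple[str, ...] = DEFAULT_ACTIVATION_MARKERS
    cytokeratins: tuple[str, ...] = DEFAULT_CYTOKERATINS

    def __post_init__(self) -> None:
        if not self.epithelial or not self.tme:
            raise ValueError("registry needs at least one phenotype per compartment")
        overlap = set(self.epithelial) & set(self.tme)
        if overlap:
            raise ValueError(f"phenotypes in both compartments: {sorted(overlap)}")
        unknown = set(self.stromal) - set(self.tme)
        if unknown:
            raise ValueError(f"stromal phenotypes not in TME list: {sorted(unknown)}")

    @property
    def all_phenotypes(self) -> tuple[str, ...]:
        return self.epithelial + self.tme

    @property
    def n_phenotypes(self) -> int:
        return len(self.epithelial) + len(self.tme)

    def compartment_of(self, phenotype: str) -> str:
        if phenotype in self.epithelial:
            return EPITHELIAL
        if phenotype in self.tme:
            return TME
        raise KeyError(f"unknown phenotype: {phenotype!r}")

    def category_map(self) -> dict[str, str]:
        """Three-way category map: epithelial / immune / stromal.

        Stromal covers fibroblast-like and endothelial phenotypes; immune is
        every remaining TME phenotype.
        """
        cats = {p: "epithelial" for p in self.epithelial}
        for p in self.tme:
            cats[p] = "stromal" if p in self.stromal else "immune"
        return cats


def make_generic_registry(n_epithelial: int, n_tme: int) -> PhenotypeRegistry:
    """Registry with numbered phenotype names, for arbitrary panel sizes."""
    epi = tuple(f"Epi_{i + 1:02d}" for i in range(n_epithelial))
    tme = tuple(f"TME_{i + 1:02d}" for i in range(n_tme))
    n_stromal = min(3, n_tme - 1) if n_tme > 1 else 0
    stromal = tme[len(tme) - n_stromal:] if n_stromal else ()
    t_cells = tme[: min(2, n_tme)]
    return PhenotypeRegistry(
        epithelial=epi, tme=tme, stromal=stromal, t_cells=t_cells
    )
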