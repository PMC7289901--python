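"""The published European-butterfly study design, as data.

The study grafted 12 subclade posteriors onto a genus-level backbone of
Papilionoidea: one unit each for Papilionidae, Pieridae and Lycaenidae,
two for Hesperiidae (Hesperiinae incl. Heteropterinae/Trapezitinae, and
Pyrginae) and seven for Nymphalidae.  This module records that design —
unit names, ingroup sizes, outgroups, attachment rules, gene panels —
together with the per-gene fragment lengths of the 12-gene supermatrix
and the table of newly sequenced island endemics.  It holds no trees:
synthetic studies borrow its structure, and tests check the package
against its printed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

#: Aligned fragment length (columns) per gene, in concatenation order.
GENE_LENGTHS: dict[str, int] = {
    "COI": 1464,
    "CAD": 850,
    "EF-1a": 1240,
    "GAPDH": 691,
    "ArgK": 596,
    "IDH": 711,
    "MDH": 733,
    "RpS2": 411,
    "RpS5": 617,
    "DDC": 373,
    "wingless": 412,
    "H3": 329,
}


@dataclass(frozen=True)
class UnitDefinition:
    """One grafting unit of the reference design (no trees attached)."""

    name: str
    family: str
    n_taxa: int
    outgroups: tuple[str, ...]
    attachment_mode: str
    attachment_note: str
    genes: tuple[str, ...]
    drop_after_outgroups: tuple[str, ...] = ()
    notes: str = ""


_ALL = tuple(GENE_LENGTHS)
_NO_H3 = tuple(g for g in _ALL if g != "H3")
_NO_DDC_H3 = tuple(g for g in _ALL if g not in ("DDC", "H3"))

#: The 12 grafting units, sorted by family as in the study description.
REFERENCE_UNITS: tuple[UnitDefinition, ...] = (
    UnitDefinition(
        name="Papilionidae",
        family="Papilionidae",
        n_taxa=36,
        outgroups=("Macrosoma tipulata", "Achlyodes busiris", "Pieris rapae"),
        attachment_mode="mrca_excluding",
        attachment_note=(
            "MRCA of all Papilionidae except Baronia brevicornis, the "
            "first-diverging (Mexican) lineage, which is also dropped "
            "from the samples before rescaling"
        ),
        genes=_NO_H3,
        drop_after_outgroups=("Baronia brevicornis",),
    ),
    UnitDefinition(
        name="Hesperiinae",
        family="Hesperiidae",
        n_taxa=169,
        outgroups=("Typhedanus ampyx", "Mylon pelopidas"),
        attachment_mode="mrca",
        attachment_note=(
            "MRCA of Hesperiinae (unit extended to Heteropterinae and "
            "Trapezitinae)"
        ),
        genes=_NO_DDC_H3,
    ),
    UnitDefinition(
        name="Pyrginae",
        family="Hesperiidae",
        n_taxa=77,
        outgroups=("Typhedanus ampyx", "Pyrrhopyge zenodorus", "Hasora khoda"),
        attachment_mode="mrca",
        attachment_note="MRCA of Pyrginae (includes Muschampia)",
        genes=_NO_DDC_H3,
    ),
    UnitDefinition(
        name="Pieridae",
        family="Pieridae",
        n_taxa=126,
        outgroups=("Bicyclus anynana", "Achlyodes busiris", "Papilio glaucus"),
        attachment_mode="mrca",
        attachment_note="MRCA of Pieridae",
        genes=_NO_H3,
    ),
    UnitDefinition(
        name="Lycaenidae",
        family="Lycaenidae",
        n_taxa=187,
        outgroups=("Bicyclus anynana", "Pieris rapae", "Hamearis lucina"),
        attachment_mode="mrca",
        attachment_note="MRCA of Lycaenidae",
        genes=_ALL,
    ),
    UnitDefinition(
        name="Danainae",
        family="Nymphalidae",
        n_taxa=7,
        outgroups=("Euploea camaralzeman", "Lycorea halia"),
        attachment_mode="mrca",
        attachment_note="MRCA of Danainae",
        genes=("COI", "CAD", "EF-1a", "GAPDH", "IDH", "MDH", "RpS2", "RpS5", "wingless"),
    ),
    UnitDefinition(
        name="Apaturinae",
        family="Nymphalidae",
        n_taxa=9,
        outgroups=("Timelaea albescens", "Biblis hyperia"),
        attachment_mode="mrca",
        attachment_note="MRCA of Apaturinae",
        genes=_NO_DDC_H3,
        notes=(
            "The source description's grafting line names Danainae here, "
            "evidently a copy error for Apaturinae; this configuration "
            "uses Apaturinae and records the discrepancy rather than "
            "silently resolving it."
        ),
    ),
    UnitDefinition(
        name="Heliconiinae+Limenitidinae",
        family="Nymphalidae",
        n_taxa=92,
        outgroups=("Amnosia decora", "Apatura iris", "Libythea celtis"),
        attachment_mode="split",
        attachment_note="the split between Limenitidinae and Heliconiinae",
        genes=_NO_H3,
    ),
    UnitDefinition(
        name="Nymphalinae",
        family="Nymphalidae",
        n_taxa=83,
        outgroups=("Historis odius", "Pycina zamba"),
        attachment_mode="mrca",
        attachment_note="MRCA of Nymphalinae",
        genes=_NO_H3,
    ),
    UnitDefinition(
        name="Satyrinae 1",
        family="Nymphalidae",
        n_taxa=13,
        outgroups=("Bicyclus anynana", "Acrophtalmia leuce", "Ragadia makuta"),
        attachment_mode="crown_of_unit",
        attachment_note=(
            "crown of the clade after outgroup removal (Kirinia, Pararge, "
            "Lasiommata, Tatinga, Chonala, Lopinga)"
        ),
        genes=("COI", "EF-1a", "GAPDH", "RpS5", "wingless"),
    ),
    UnitDefinition(
        name="Satyrinae 2",
        family="Nymphalidae",
        n_taxa=161,
        outgroups=("Coenonympha pamphilus", "Taygetis virgilia", "Pronophila thelebe"),
        attachment_mode="crown_of_unit",
        attachment_note="crown of the clade after outgroup removal",
        genes=_NO_DDC_H3,
    ),
    UnitDefinition(
        name="Satyrinae 3",
        family="Nymphalidae",
        n_taxa=15,
        outgroups=("Sinonympha amoena", "Oressinoma sorata"),
        attachment_mode="crown_of_unit",
        attachment_note="crown of Coenonympha",
        genes=("COI", "CAD", "EF-1a", "GAPDH", "IDH", "MDH", "RpS2", "RpS5", "wingless"),
    ),
)

#: Backbone-level tip substitution: the single European Charaxinae takes
#: the position of its close relative already present in the backbone.
BACKBONE_SUBSTITUTIONS: dict[str, str] = {
    "Charaxes castor": "Charaxes jasius",
}

#: Replicate count of the grafting loop in the published analysis.
N_REPLICATES = 1000

#: Species count of the final regional panel.
N_PANEL_SPECIES = 496


def reference_unit_sizes() -> dict[str, int]:
    """Unit name → ingroup taxon count, e.g. for sizing synthetic studies."""
    return {u.name: u.n_taxa for u in REFERENCE_UNITS}


def load_new_species_table() -> pd.DataFrame:
    """The newly sequenced species with no previously published data.

    Columns: taxon, origin, and one GenBank accession column per gene
    that was sequenced (empty where a gene is missing)."""
    with resources.files("phylograft").joinpath(
        "data/table1_new_species.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")
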