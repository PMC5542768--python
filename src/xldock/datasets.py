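"""Packaged fixture tables.

These are *curated transcriptions* of published experimental outcomes —
pair-wise crosslink hit lists, a partial photo-crosslink footprint table,
a receptor generic-numbering map and a homologous-position remap between
the two agonist peptides.  They are data inputs, not computed results; the
footprint table covers only residues named explicitly in the source text
and is therefore partial.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .footprints import FootprintSet
from .restraints import PairwiseHit, RestraintSet
from .structures import GenericNumberMap, ResidueRef

__all__ = [
    "numbering_map",
    "pairwise_hits",
    "curated_footprints",
    "ucn1_restraints",
    "crf_to_ucn1_remap",
]


def _open(name: str):
    return resources.files("xldock.data").joinpath(name).open("r")


def numbering_map() -> GenericNumberMap:
    """Receptor generic numbers and domain tags for the mapped positions."""
    with _open("numbering_map.csv") as fh:
        return GenericNumberMap.from_csv(fh)


def pairwise_hits(which: str = "CRF") -> list[PairwiseHit]:
    """Pair-wise crosslink hit list for ``CRF`` (7 pairs, all Lys(ClAc)-Cys)
    or ``antagonist`` (15 pairs, three N-terminal ClAc entries)."""
    files = {"CRF": "crf_pairwise_hits.csv", "antagonist": "antagonist_pairwise_hits.csv"}
    if which not in files:
        raise ValueError(f"which must be one of {sorted(files)}")
    with _open(files[which]) as fh:
        df = pd.read_csv(fh, dtype={"ligand_chain": str, "receptor_chain": str})
    return [
        PairwiseHit(
            ligand_id=row.ligand,
            ligand_residue=ResidueRef(
                row.ligand_chain, int(row.ligand_seq), res_name=row.ligand_res
            ),
            receptor_residue=ResidueRef(
                row.receptor_chain, int(row.receptor_seq), res_name=row.receptor_res
            ),
            crosslinker=row.crosslinker,
        )
        for row in df.itertuples()
    ]


def curated_footprints() -> FootprintSet:
    """Partial photo-crosslink footprints for the five peptide ligands."""
    with _open("curated_footprints.csv") as fh:
        return FootprintSet.from_csv(fh)


def ucn1_restraints() -> RestraintSet:
    """Cβ-Cβ restraints of the companion agonist complex (9 Å bounds)."""
    with _open("ucn1_pairwise_restraints.csv") as fh:
        return RestraintSet.from_csv(fh)


def crf_to_ucn1_remap() -> dict[int, int]:
    """Homologous ligand positions: CRF residue number → Ucn1 residue number."""
    with _open("remap_crf_to_ucn1.csv") as fh:
        df = pd.read_csv(fh)
    return {int(r.from_seq): int(r.to_seq) for r in df.itertuples()}
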