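"""Crosslink hit calling and ligand footprint comparison.

A positional photo-crosslinking scan yields, per ligand, a band intensity
for every scanned receptor position.  A position is called a *hit* when
its intensity is higher than a threshold defined as a fraction (default
50%) of the most intense signal for that ligand.  The resulting per-ligand
residue sets — footprints — are compared by exact set algebra and
summarised per receptor domain (helix I-VII, ECL1-3, ECD, hinge) through a
generic-numbering map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .structures import GenericNumberMap

__all__ = [
    "IntensityTable",
    "HitCallingConfig",
    "FootprintResidue",
    "FootprintSet",
    "FootprintComparison",
    "call_hits",
    "compare_footprints",
    "domain_summary",
]


class IntensityTable:
    """Quantified band intensities: one row per (ligand, receptor residue).

    CSV format: ``ligand,chain,seq,intensity`` with header.  Intensities
    are arbitrary units, non-negative; densitometry itself is upstream.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        required = {"ligand", "chain", "seq", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"intensity table missing columns {sorted(missing)}")
        df = df.copy()
        df["seq"] = df["seq"].astype(int)
        df["intensity"] = df["intensity"].astype(float)
        if (df["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if df.duplicated(subset=["ligand", "chain", "seq"]).any():
            raise ValueError("duplicate (ligand, residue) rows in intensity table")
        self.df = df
        self.provenance = provenance

    @classmethod
    def from_csv(cls, path_or_buf, provenance: str = "") -> "IntensityTable":
        return cls(pd.read_csv(path_or_buf, dtype={"chain": str}), provenance)

    def to_csv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, index=False)

    def ligands(self) -> list[str]:
        return list(dict.fromkeys(self.df["ligand"]))


@dataclass(frozen=True)
class HitCallingConfig:
    """Threshold as a fraction of the per-ligand maximum (default 0.5).

    ``strict`` keeps the published convention of *strictly greater than*
    the threshold; set False for a ≥ comparison in sensitivity analyses.
    """

    threshold_fraction: float = 0.5
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FootprintResidue:
    chain: str
    seq: int
    icode: str = ""
    generic: str | None = None
    domain: str | None = None


class FootprintSet:
    """Per-ligand sets of receptor residues called as crosslink hits."""

    def __init__(self, hits: dict[str, set[FootprintResidue]] | None = None):
        self.hits: dict[str, set[FootprintResidue]] = {
            k: set(v) for k, v in (hits or {}).items()
        }

    def ligands(self) -> list[str]:
        return list(self.hits)

    def residues(self, ligand_id: str) -> set[FootprintResidue]:
        if ligand_id not in self.hits:
            raise KeyError(f"no footprint recorded for ligand {ligand_id!r}")
        return set(self.hits[ligand_id])

    def positions(self, ligand_id: str) -> set[tuple[str, int]]:
        return {(r.chain, r.seq) for r in self.residues(ligand_id)}

    def annotated(self, m: GenericNumberMap) -> "FootprintSet":
        """Return a copy with generic/domain tags filled from the map."""
        out: dict[str, set[FootprintResidue]] = {}
        for ligand, residues in self.hits.items():
            out[ligand] = {
                FootprintResidue(
                    r.chain,
                    r.seq,
                    r.icode,
                    generic=m.generic_for(r.chain, r.seq),
                    domain=m.domain_for(r.chain, r.seq),
                )
                for r in residues
            }
        return FootprintSet(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ligand in self.hits:
            for r in sorted(self.hits[ligand], key=lambda r: (r.chain, r.seq)):
                rows.append(
                    {
                        "ligand": ligand,
                        "chain": r.chain,
                        "seq": r.seq,
                        "generic": r.generic or "",
                        "domain": r.domain or "",
                    }
                )
        return pd.DataFrame(rows, columns=["ligand", "chain", "seq", "generic", "domain"])

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "FootprintSet":
        df = pd.read_csv(path_or_buf, dtype={"chain": str, "generic": str, "domain": str})
        hits: dict[str, set[FootprintResidue]] = {}
        for row in df.itertuples():
            generic = row.generic if isinstance(row.generic, str) and row.generic else None
            domain = row.domain if isinstance(row.domain, str) and row.domain else None
            hits.setdefault(row.ligand, set()).add(
                FootprintResidue(row.chain, int(row.seq), generic=generic, domain=domain)
            )
        return cls(hits)


def call_hits(t: IntensityTable, c: HitCallingConfig = HitCallingConfig()) -> FootprintSet:
    """Call hits at a fraction of the per-ligand maximum intensity.

    Per ligand: threshold = threshold_fraction x max intensity; a position
    is a hit iff its intensity exceeds the threshold (strictly by default).
    A ligand whose intensities are all zero yields an empty set with a
    warning — an all-dark blot is degenerate, not an error.
    """
    hits: dict[str, set[FootprintResidue]] = {}
    for ligand, group in t.df.groupby("ligand", sort=False):
        peak = group["intensity"].max()
        if peak <= 0:
            warnings.warn(f"ligand {ligand!r}: all intensities zero; empty hit set")
            hits[ligand] = set()
            continue
        threshold = c.threshold_fraction * peak
        if c.strict:
            selected = group[group["intensity"] > threshold]
        else:
            selected = group[group["intensity"] >= threshold]
        hits[ligand] = {
            FootprintResidue(row.chain, int(row.seq)) for row in selected.itertuples()
        }
    return FootprintSet(hits)


@dataclass
class FootprintComparison:
    """Exact set algebra between two ligand footprints."""

    ligand_a: str
    ligand_b: str
    shared: set[FootprintResidue]
    only_a: set[FootprintResidue]
    only_b: set[FootprintResidue]
    domain_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.only_a) + len(self.only_b)


def _key(r: FootprintResidue) -> tuple[str, int, str]:
    return (r.chain, r.seq, r.icode)


def compare_footprints(a: FootprintSet, b: FootprintSet, ligand_a: str, ligand_b: str) -> FootprintComparison:
    """Partition the union of two footprints into shared / only-a / only-b."""
    res_a = {_key(r): r for r in a.residues(ligand_a)}
    res_b = {_key(r): r for r in b.residues(ligand_b)}
    shared = {res_a[k] for k in res_a.keys() & res_b.keys()}
    only_a = {res_a[k] for k in res_a.keys() - res_b.keys()}
    only_b = {res_b[k] for k in res_b.keys() - res_a.keys()}
    counts: dict[str, dict[str, int]] = {}
    for name, residues in (("shared", shared), ("only_a", only_a), ("only_b", only_b)):
        per_domain: dict[str, int] = {}
        for r in residues:
            per_domain[r.domain or "unmapped"] = per_domain.get(r.domain or "unmapped", 0) + 1
        counts[name] = per_domain
    return FootprintComparison(ligand_a, ligand_b, shared, only_a, only_b, counts)


def domain_summary(
    f: FootprintSet, m: GenericNumberMap, ligand_id: str
) -> tuple[dict[str, int], list[tuple[str, int]]]:
    """Hit counts per receptor domain; unmapped residues listed separately."""
    counts: dict[str, int] = {}
    unmapped: list[tuple[str, int]] = []
    for r in f.residues(ligand_id):
        domain = m.domain_for(r.chain, r.seq)
        if domain is None:
            unmapped.append((r.chain, r.seq))
        else:
            counts[domain] = counts.get(domain, 0) + 1
    return counts, sorted(unmapped)
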