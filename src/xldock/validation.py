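"""Restraint-satisfaction measurement and cross-validation.

Two kinds of checks mirror the two crosslinking experiments:

* pair-wise restraints (Cβ-Cβ or Nα-Cβ) are measured directly between
  their anchor atoms and satisfied when d ≤ d0 (inclusive; the penalty is
  zero at the threshold);
* photo-crosslink hits are validated by the distance from the hit
  residue's Cβ to the *nearest heavy atom* of the ligand, against the
  ~9 Å probe radius.

``cross_validate`` measures one complex's restraint set inside a different
model after remapping ligand positions through an explicit homologous-
position table (e.g. H13 in one peptide ↔ H12 in its paralog); rows whose
position cannot be mapped are reported as untestable, never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .footprints import FootprintSet
from .restraints import DistanceRestraint, RestraintSet
from .structures import Structure, distance, get_anchor_atom

__all__ = [
    "RestraintMeasurement",
    "SatisfactionReport",
    "PhotoValidationReport",
    "measure_restraints",
    "validate_photo",
    "cross_validate",
]


@dataclass
class RestraintMeasurement:
    restraint: DistanceRestraint
    distance: float
    satisfied: bool
    margin: float  # d - d0; positive means violated
    testable: bool = True
    note: str = ""


@dataclass
class SatisfactionReport:
    """Per-restraint distances plus aggregate satisfaction counts."""

    rows: list[RestraintMeasurement]
    slack: float = 0.0

    @property
    def n_total(self) -> int:
        return sum(1 for r in self.rows if r.testable)

    @property
    def n_satisfied(self) -> int:
        return sum(1 for r in self.rows if r.testable and r.satisfied)

    @property
    def n_untestable(self) -> int:
        return sum(1 for r in self.rows if not r.testable)

    @property
    def max_violation(self) -> float:
        margins = [r.margin for r in self.rows if r.testable and not r.satisfied]
        return max(margins) if margins else 0.0

    @property
    def all_satisfied(self) -> bool:
        return self.n_satisfied == self.n_total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.rows:
            r = m.restraint
            rows.append(
                {
                    "label": r.label,
                    "ligand": f"{r.chain_a}/{r.seq_a}{r.icode_a}:{r.anchor_a}",
                    "receptor": f"{r.chain_b}/{r.seq_b}{r.icode_b}:{r.anchor_b}",
                    "d0": r.d0,
                    # text output rounds to 0.1 Å; JSON keeps full precision
                    "distance": round(m.distance, 1) if m.testable else np.nan,
                    "satisfied": m.satisfied if m.testable else None,
                    "margin": round(m.margin, 1) if m.testable else np.nan,
                    "testable": m.testable,
                    "note": m.note,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "n_total": self.n_total,
            "n_satisfied": self.n_satisfied,
            "n_untestable": self.n_untestable,
            "max_violation": self.max_violation,
            "slack": self.slack,
            "rows": [
                {
                    "label": m.restraint.label,
                    "d0": m.restraint.d0,
                    "distance": m.distance if m.testable else None,
                    "satisfied": m.satisfied if m.testable else None,
                    "margin": m.margin if m.testable else None,
                    "testable": m.testable,
                    "note": m.note,
                }
                for m in self.rows
            ],
        }
        return json.dumps(payload, indent=2)


def measure_restraints(s: Structure, rs: RestraintSet, slack: float = 0.0) -> SatisfactionReport:
    """Measure every restraint between its anchor atoms.

    ``slack`` loosens the satisfied test to d ≤ d0 + slack without touching
    the recorded margins (default 0: the printed threshold is the test).
    """
    rows = []
    for r in rs:
        (ca, sa, ia, aa), (cb, sb, ib, ab) = r.anchors()
        atom_a = get_anchor_atom(s, (ca, sa, ia), aa)
        atom_b = get_anchor_atom(s, (cb, sb, ib), ab)
        d = distance(atom_a, atom_b)
        rows.append(
            RestraintMeasurement(
                restraint=r,
                distance=d,
                satisfied=d <= r.d0 + slack,
                margin=d - r.d0,
            )
        )
    return SatisfactionReport(rows, slack=slack)


@dataclass
class PhotoHitMeasurement:
    chain: str
    seq: int
    generic: str | None
    distance: float  # Cβ to nearest ligand heavy atom
    satisfied: bool


@dataclass
class PhotoValidationReport:
    """Per-footprint-residue minimum heavy-atom distances vs the probe radius."""

    radius: float
    ligand_chain: str
    rows: list[PhotoHitMeasurement] = field(default_factory=list)

    @property
    def violators(self) -> list[PhotoHitMeasurement]:
        return [r for r in self.rows if not r.satisfied]

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_satisfied(self) -> int:
        return sum(1 for r in self.rows if r.satisfied)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": r.chain,
                    "seq": r.seq,
                    "generic": r.generic,
                    "min_distance": round(r.distance, 1),
                    "satisfied": r.satisfied,
                }
                for r in self.rows
            ]
        )


def validate_photo(
    s: Structure,
    f: FootprintSet,
    ligand_id: str,
    radius: float = 9.0,
    ligand_chain: str = "L",
) -> PhotoValidationReport:
    """Check photo-crosslink hits against the probe reach.

    For each hit residue the distance from its Cβ (virtual for glycine) to
    the nearest non-hydrogen atom of the ligand chain must not exceed
    ``radius`` (default 9 Å).
    """
    ligand_coords = s.coords(chain=ligand_chain, heavy_only=True)
    if ligand_coords.shape[0] == 0:
        raise ValueError(f"ligand chain {ligand_chain!r} has no heavy atoms")
    report = PhotoValidationReport(radius=radius, ligand_chain=ligand_chain)
    for hit in f.residues(ligand_id):
        cb = get_anchor_atom(s, (hit.chain, hit.seq, hit.icode), "CB")
        dmin = float(np.min(np.linalg.norm(ligand_coords - cb.xyz, axis=1)))
        report.rows.append(
            PhotoHitMeasurement(
                chain=hit.chain,
                seq=hit.seq,
                generic=hit.generic,
                distance=dmin,
                satisfied=dmin <= radius,
            )
        )
    return report


def cross_validate(
    s: Structure,
    foreign_rs: RestraintSet,
    remap: dict[int, int] | None = None,
    ligand_chain: str | None = None,
    slack: float = 0.0,
) -> SatisfactionReport:
    """Measure a foreign restraint set in this model after position remap.

    ``remap`` maps the foreign ligand's residue numbers onto this model's
    ligand numbering (an explicit homologous-position table, e.g. {13: 12}
    for an offset-by-one peptide pair).  An identity map is assumed where
    ``remap`` is None.  Receptor positions are shared and pass through
    unchanged.  Restraints whose ligand position has no image in the map or
    whose anchors are missing in the model are marked untestable.
    """
    rows = []
    remap = remap if remap is not None else {}
    for r in foreign_rs:
        seq_mapped = remap.get(r.seq_a, r.seq_a if not remap else None)
        if seq_mapped is None:
            rows.append(
                RestraintMeasurement(
                    restraint=r,
                    distance=float("nan"),
                    satisfied=False,
                    margin=float("nan"),
                    testable=False,
                    note=f"no homologous position for ligand residue {r.seq_a}",
                )
            )
            continue
        chain_a = ligand_chain if ligand_chain is not None else r.chain_a
        try:
            atom_a = get_anchor_atom(s, (chain_a, seq_mapped, r.icode_a), r.anchor_a)
            atom_b = get_anchor_atom(s, (r.chain_b, r.seq_b, r.icode_b), r.anchor_b)
        except (KeyError, ValueError) as exc:
            rows.append(
                RestraintMeasurement(
                    restraint=r,
                    distance=float("nan"),
                    satisfied=False,
                    margin=float("nan"),
                    testable=False,
                    note=str(exc),
                )
            )
            continue
        d = distance(atom_a, atom_b)
        rows.append(
            RestraintMeasurement(
                restraint=r,
                distance=d,
                satisfied=d <= r.d0 + slack,
                margin=d - r.d0,
                note=f"ligand {r.seq_a} -> {seq_mapped}" if seq_mapped != r.seq_a else "",
            )
        )
    return SatisfactionReport(rows, slack=slack)
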