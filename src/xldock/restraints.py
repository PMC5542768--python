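"""Crosslinker geometry, linker-reach sampling and flat-bottom restraints.

Three crosslink chemistries are modelled:

``AZI_PHOTO``
    p-azido-Phe photo-crosslinking.  A proximity probe: on activation it
    captures any nearby ligand heavy atom within ~9 Å of its Cβ.  Used for
    *validation only*, never as a docking restraint.
``LYS_CLAC_CYS``
    A chloroacetamide carried on a lysine side chain reacting with a
    receptor cysteine thiol.  The crosslinked product spans the chain
    Cβ-Cγ-Cδ-Cε-Nζ-C(O)-CH2-S-Cβ; the Cβ-Cβ distance compatible with the
    reaction is bounded by ~10 Å.
``NTERM_CLAC_CYS``
    Chloroacetyl on the peptide N-terminal amine reacting with a cysteine:
    product chain Nα-C(O)-CH2-S-Cβ, bounding the Nα-Cβ distance at ~5 Å.

Reach is estimated by Monte Carlo over the rotatable torsions of the
product chain with fixed ideal bond lengths and angles (free-molecule
assumption, no Boltzmann weighting); amide torsions stay trans.  Restraints
derived from pair-wise hits are upper-bound flat-bottom harmonics:
E = 0 for d ≤ d0 and k (d - d0)² above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import ResidueRef, Structure

__all__ = [
    "LinkerAtom",
    "CrosslinkerSpec",
    "PairwiseHit",
    "DistanceRestraint",
    "RestraintSet",
    "ReachDistribution",
    "default_registry",
    "load_specs",
    "linker_reach",
    "reach_grid",
    "extended_reach",
    "build_restraints",
    "penalty",
    "total_restraint_energy",
]

#: Default harmonic weight (energy/Å²), matching the restrained-MD weight.
DEFAULT_K = 10.0


@dataclass(frozen=True)
class LinkerAtom:
    """One chain atom after the first: bond to predecessor + angle at it."""

    label: str
    bond_length: float  # Å, to the previous chain atom
    bond_angle: float  # degrees, previous-previous / previous / this

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError(f"bond length must be positive ({self.label})")
        if not 0 < self.bond_angle < 180:
            raise ValueError(f"bond angle must be in (0, 180) ({self.label})")


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Chemistry of one crosslink type.

    ``linker_template`` lists the chain atoms between (and including) the
    two anchors.  ``rotatable`` indexes the free torsions (torsion *i*
    places chain atom *i* + 3); torsions not listed are held trans (180°),
    which keeps amide bonds planar.
    """

    name: str
    ligand_anchor: str  # anchor kind on the peptide side: CB / N / CA
    receptor_anchor: str
    d0: float  # maximum reach in Å (restraint threshold)
    linker_template: tuple[LinkerAtom, ...] = ()
    rotatable: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        n_torsions = max(len(self.linker_template) - 2, 0)
        for idx in self.rotatable:
            if not 0 <= idx < n_torsions:
                raise ValueError(f"rotatable torsion index {idx} out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.linker_template) + 1

    def bond_lengths(self) -> np.ndarray:
        return np.array([a.bond_length for a in self.linker_template])

    def bond_angles(self) -> np.ndarray:
        return np.array([a.bond_angle for a in self.linker_template[1:]])


def _lys_clac_cys_template() -> tuple[tuple[LinkerAtom, ...], tuple[int, ...]]:
    # Lys side chain from Cβ, alkylated Nζ amide, thioether to the Cys Cβ.
    # Ideal values: aliphatic C-C 1.53 Å / 111°, C-N 1.47 Å, amide C-N
    # 1.35 Å with sp2 angles (121.7° at N, 116.5° at C'), C-S 1.81 Å,
    # thioether C-S-C 98.9°.  The carbonyl O is off-path.
    atoms = (
        LinkerAtom("CG", 1.53, 111.0),
        LinkerAtom("CD", 1.53, 111.0),
        LinkerAtom("CE", 1.53, 111.0),
        LinkerAtom("NZ", 1.47, 111.0),
        LinkerAtom("C", 1.35, 121.7),  # amide carbonyl carbon
        LinkerAtom("CH2", 1.52, 116.5),
        LinkerAtom("SG", 1.81, 112.4),
        LinkerAtom("CB2", 1.81, 98.9),
    )
    # torsion i places atom i+3 of [CB, CG, CD, CE, NZ, C, CH2, SG, CB2];
    # index 3 is the amide (NZ-C) torsion, held trans.
    rotatable = (0, 1, 2, 4, 5)
    return atoms, rotatable


def _nterm_clac_cys_template() -> tuple[tuple[LinkerAtom, ...], tuple[int, ...]]:
    # Chloroacetylated N-terminus: Nα-C(O)-CH2-S-Cβ.
    atoms = (
        LinkerAtom("C", 1.35, 121.7),  # first atom's angle column is unused
        LinkerAtom("CH2", 1.52, 116.5),
        LinkerAtom("SG", 1.81, 112.4),
        LinkerAtom("CB", 1.81, 98.9),
    )
    # chain [N, C, CH2, SG, CB]: torsion 0 places SG (about C-CH2),
    # torsion 1 places CB (about CH2-SG); the Nα-C amide axis torsion does
    # not exist inside this chain.
    rotatable = (0, 1)
    return atoms, rotatable


def default_registry() -> dict[str, CrosslinkerSpec]:
    """Built-in crosslinker registry with field-standard defaults."""
    lys_t, lys_rot = _lys_clac_cys_template()
    nterm_t, nterm_rot = _nterm_clac_cys_template()
    return {
        "AZI_PHOTO": CrosslinkerSpec(
            name="AZI_PHOTO",
            ligand_anchor="CB",  # probe Cβ to nearest ligand heavy atom
            receptor_anchor="CB",
            d0=9.0,
        ),
        "LYS_CLAC_CYS": CrosslinkerSpec(
            name="LYS_CLAC_CYS",
            ligand_anchor="CB",
            receptor_anchor="CB",
            d0=10.0,
            linker_template=lys_t,
            rotatable=lys_rot,
        ),
        "NTERM_CLAC_CYS": CrosslinkerSpec(
            name="NTERM_CLAC_CYS",
            ligand_anchor="N",
            receptor_anchor="CB",
            d0=5.0,
            linker_template=nterm_t,
            rotatable=nterm_rot,
        ),
    }


def load_specs(path_or_buf) -> dict[str, CrosslinkerSpec]:
    """Read a crosslinker registry from JSON."""
    if hasattr(path_or_buf, "read"):
        data = json.load(path_or_buf)
    else:
        with open(path_or_buf) as fh:
            data = json.load(fh)
    registry = {}
    for entry in data:
        template = tuple(
            LinkerAtom(a["label"], float(a["bond_length"]), float(a["bond_angle"]))
            for a in entry.get("linker_template", [])
        )
        registry[entry["name"]] = CrosslinkerSpec(
            name=entry["name"],
            ligand_anchor=entry["ligand_anchor"],
            receptor_anchor=entry["receptor_anchor"],
            d0=float(entry["d0"]),
            linker_template=template,
            rotatable=tuple(entry.get("rotatable", [])),
        )
    return registry


def dump_specs(registry: dict[str, CrosslinkerSpec]) -> str:
    out = []
    for spec in registry.values():
        out.append(
            {
                "name": spec.name,
                "ligand_anchor": spec.ligand_anchor,
                "receptor_anchor": spec.receptor_anchor,
                "d0": spec.d0,
                "linker_template": [
                    {"label": a.label, "bond_length": a.bond_length, "bond_angle": a.bond_angle}
                    for a in spec.linker_template
                ],
                "rotatable": list(spec.rotatable),
            }
        )
    return json.dumps(out, indent=2)


# ---------------------------------------------------------------------------
# Reach sampling


def chain_end_distances(
    bonds: Sequence[float], angles: Sequence[float], torsions: np.ndarray
) -> np.ndarray:
    """End-to-end distances of an internal-coordinate chain (vectorized NeRF).

    ``torsions`` has shape (m, n_atoms - 3) in degrees; row torsion *i*
    places chain atom *i* + 3.
    """
    bonds = np.asarray(bonds, float)
    angles = np.asarray(angles, float)
    T = np.atleast_2d(np.asarray(torsions, float))
    n = len(bonds) + 1
    if n < 2:
        raise ValueError("template must define at least one bond")
    m = T.shape[0]
    if n == 2:
        return np.full(m, bonds[0])
    prev2 = np.zeros((m, 3))
    prev1 = np.zeros((m, 3))
    prev1[:, 0] = bonds[0]
    ang = np.radians(angles[0])
    cur = prev1 + bonds[1] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    start = np.zeros((m, 3))
    for i in range(3, n):
        b = bonds[i - 1]
        theta = np.radians(angles[i - 2])
        phi = np.radians(T[:, i - 3])
        bc = cur - prev1
        bc /= np.linalg.norm(bc, axis=1, keepdims=True)
        nvec = np.cross(prev1 - prev2, bc)
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        mvec = np.cross(nvec, bc)
        nxt = (
            cur
            + (-b * np.cos(theta)) * bc
            + (b * np.sin(theta) * np.cos(phi))[:, None] * mvec
            + (b * np.sin(theta) * np.sin(phi))[:, None] * nvec
        )
        prev2, prev1, cur = prev1, cur, nxt
    return np.linalg.norm(cur - start, axis=1)


def _torsion_matrix(spec: CrosslinkerSpec, values: np.ndarray) -> np.ndarray:
    n_torsions = max(spec.n_atoms - 3, 0)
    T = np.full((values.shape[0], n_torsions), 180.0)
    if spec.rotatable:
        T[:, list(spec.rotatable)] = values
    return T


@dataclass
class ReachDistribution:
    """Sampled anchor-anchor distances for one crosslinker."""

    spec_name: str
    samples: np.ndarray
    n_samples: int
    seed: int
    percentile_levels: tuple[float, ...] = (50.0, 90.0, 95.0, 99.0)

    @property
    def max(self) -> float:
        return float(self.samples.max())

    @property
    def percentiles(self) -> dict[float, float]:
        return {p: float(np.percentile(self.samples, p)) for p in self.percentile_levels}

    def summary(self) -> dict:
        return {
            "crosslinker": self.spec_name,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "max": self.max,
            "percentiles": {str(k): v for k, v in self.percentiles.items()},
        }


def linker_reach(
    spec: CrosslinkerSpec, n_samples: int = 100_000, seed: int = 0, chunk: int = 200_000
) -> ReachDistribution:
    """Monte Carlo reach of the crosslinked product.

    Rotatable torsions are drawn i.i.d. uniform on (-180°, 180°]; fixed
    torsions stay trans.  Deterministic for a given seed.  The sampled
    maximum approaches the geometric maximum from below and never exceeds
    the sum of bond lengths.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not spec.linker_template:
        raise ValueError(f"crosslinker {spec.name} has no linker template")
    rng = np.random.default_rng(seed)
    bonds = spec.bond_lengths()
    angles = spec.bond_angles()
    out = np.empty(n_samples)
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        values = rng.uniform(-180.0, 180.0, size=(m, len(spec.rotatable)))
        out[done : done + m] = chain_end_distances(bonds, angles, _torsion_matrix(spec, values))
        done += m
    return ReachDistribution(spec.name, out, n_samples, seed)


def reach_grid(spec: CrosslinkerSpec, step_deg: float = 15.0, chunk: int = 500_000) -> float:
    """Maximum reach over an exhaustive grid of the rotatable torsions.

    Independent check on the Monte Carlo estimate; the grid includes the
    trans (180°) point of every torsion.
    """
    if not spec.linker_template:
        raise ValueError(f"crosslinker {spec.name} has no linker template")
    bonds = spec.bond_lengths()
    angles = spec.bond_angles()
    n_rot = len(spec.rotatable)
    if n_rot == 0:
        return float(chain_end_distances(bonds, angles, _torsion_matrix(spec, np.empty((1, 0)))))
    axis = np.arange(-180.0 + step_deg, 180.0 + 1e-9, step_deg)
    k = len(axis)
    total = k**n_rot
    best = 0.0
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        idx = np.arange(lo, hi)
        combo = np.empty((hi - lo, n_rot))
        for j in range(n_rot):
            combo[:, n_rot - 1 - j] = axis[idx % k]
            idx //= k
        d = chain_end_distances(bonds, angles, _torsion_matrix(spec, combo))
        best = max(best, float(d.max()))
    return best


def extended_reach(spec: CrosslinkerSpec) -> float:
    """Reach of the planar all-trans conformer (near-maximal extension)."""
    T = np.full((1, max(spec.n_atoms - 3, 0)), 180.0)
    return float(chain_end_distances(spec.bond_lengths(), spec.bond_angles(), T)[0])


# ---------------------------------------------------------------------------
# Restraints


@dataclass(frozen=True)
class PairwiseHit:
    """One observed ligand-receptor crosslink pair."""

    ligand_id: str
    ligand_residue: ResidueRef
    receptor_residue: ResidueRef
    crosslinker: str


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper-bound flat-bottom harmonic between two anchor atoms."""

    chain_a: str
    seq_a: int
    anchor_a: str
    chain_b: str
    seq_b: int
    anchor_b: str
    d0: float
    k: float = DEFAULT_K
    icode_a: str = ""
    icode_b: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def anchors(self) -> tuple[tuple[str, int, str, str], tuple[str, int, str, str]]:
        return (
            (self.chain_a, self.seq_a, self.icode_a, self.anchor_a),
            (self.chain_b, self.seq_b, self.icode_b, self.anchor_b),
        )


class RestraintSet:
    """Ordered collection of distance restraints with CSV round-trip."""

    COLUMNS = [
        "ligand_chain",
        "ligand_seq",
        "ligand_anchor",
        "receptor_chain",
        "receptor_seq",
        "receptor_anchor",
        "d0",
        "k",
    ]

    def __init__(self, restraints: Iterable[DistanceRestraint] = ()):
        self.restraints: list[DistanceRestraint] = list(restraints)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ligand_chain": r.chain_a,
                "ligand_seq": r.seq_a,
                "ligand_anchor": r.anchor_a,
                "receptor_chain": r.chain_b,
                "receptor_seq": r.seq_b,
                "receptor_anchor": r.anchor_b,
                "d0": r.d0,
                "k": r.k,
            }
            for r in self.restraints
        ]
        return pd.DataFrame(rows, columns=self.COLUMNS)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RestraintSet":
        df = pd.read_csv(path_or_buf, dtype={"ligand_chain": str, "receptor_chain": str})
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"restraint CSV missing columns {sorted(missing)}")
        return cls(
            DistanceRestraint(
                chain_a=row.ligand_chain,
                seq_a=int(row.ligand_seq),
                anchor_a=row.ligand_anchor,
                chain_b=row.receptor_chain,
                seq_b=int(row.receptor_seq),
                anchor_b=row.receptor_anchor,
                d0=float(row.d0),
                k=float(row.k),
            )
            for row in df.itertuples()
        )


def build_restraints(
    hits: Iterable[PairwiseHit],
    specs: dict[str, CrosslinkerSpec] | None = None,
    k_default: float = DEFAULT_K,
) -> RestraintSet:
    """One flat-bottom restraint per pair-wise hit.

    Anchor kinds and d0 come from the hit's crosslinker spec: Cβ-Cβ at
    10 Å for Lys(ClAc)-Cys, Nα-Cβ at 5 Å for the N-terminal variant.
    """
    specs = specs if specs is not None else default_registry()
    restraints = []
    for hit in hits:
        if hit.crosslinker not in specs:
            raise KeyError(
                f"unknown crosslinker {hit.crosslinker!r} for hit "
                f"{hit.ligand_residue}-{hit.receptor_residue}"
            )
        spec = specs[hit.crosslinker]
        restraints.append(
            DistanceRestraint(
                chain_a=hit.ligand_residue.chain,
                seq_a=hit.ligand_residue.seq,
                anchor_a=spec.ligand_anchor,
                chain_b=hit.receptor_residue.chain,
                seq_b=hit.receptor_residue.seq,
                anchor_b=spec.receptor_anchor,
                d0=spec.d0,
                k=k_default,
                icode_a=hit.ligand_residue.icode,
                icode_b=hit.receptor_residue.icode,
                label=f"{hit.ligand_id}:{hit.ligand_residue.res_name or ''}"
                f"{hit.ligand_residue.seq}-{hit.receptor_residue.res_name or ''}"
                f"{hit.receptor_residue.seq}",
            )
        )
    return RestraintSet(restraints)


def penalty(r: DistanceRestraint, d: float) -> float:
    """Flat-bottom harmonic: 0 for d ≤ d0, k (d - d0)² beyond."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    excess = d - r.d0
    return 0.0 if excess <= 0 else r.k * excess * excess


def total_restraint_energy(s: Structure, rs: RestraintSet):
    """Sum of per-restraint penalties plus the per-restraint report."""
    from .validation import measure_restraints  # local import avoids a cycle

    report = measure_restraints(s, rs)
    energy = sum(penalty(r, row.distance) for r, row in zip(rs, report.rows))
    return energy, report
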