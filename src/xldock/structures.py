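"""Coordinate data model and PDB I/O for crosslink-based modelling.

The containers here are deliberately small: an ordered list of residues,
each holding its atoms, is all the rest of the pipeline needs.  Residues
are always addressed by *author* numbering (chain, seq, icode), matching
how crosslinking positions are reported (e.g. F330 in helix VI).  Class-B
generic numbers ("Wootten" labels such as ``6.56``) are carried as optional
annotations attached via :class:`GenericNumberMap`.

PDB text is parsed through :mod:`gemmi`; multi-model files become a
:class:`Trajectory` whose frames share one topology.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "Structure",
    "Trajectory",
    "GenericNumberMap",
    "read_pdb",
    "write_pdb",
    "distance",
    "get_anchor_atom",
    "virtual_cbeta",
    "annotate",
]

#: Ideal Cα-Cβ bond length (Å) used when constructing a virtual Cβ.
CA_CB_LENGTH = 1.53
#: Ideal tetrahedral angle (degrees) at Cα for the virtual Cβ.
TETRAHEDRAL_ANGLE = 109.5

_HYDROGEN_ELEMENTS = {"H", "D"}

GUESSABLE = {"N", "C", "O", "S", "P", "H"}


@dataclass
class AtomRecord:
    """One atom: serial, PDB atom name, element and Cartesian coordinates (Å)."""

    serial: int
    name: str
    element: str
    xyz: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not self.element:
            self.element = _element_from_name(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


def _element_from_name(name: str) -> str:
    """Derive the element symbol from a PDB atom name (first alpha character)."""
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter elements in protein context are rare; single letter works
            # for N/C/O/S/H and the Cβ/Cγ style names used throughout.
            return ch.upper()
    raise ValueError(f"cannot derive element from atom name {name!r}")


@dataclass(frozen=True)
class ResidueRef:
    """Author-numbered residue reference; generic label is annotation only."""

    chain: str
    seq: int
    icode: str = ""
    res_name: str = field(default="", compare=False)
    generic: str | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.icode)

    def __str__(self) -> str:  # e.g. R/F330 or R/330
        label = f"{self.chain}/{self.res_name or ''}{self.seq}{self.icode}"
        return label + (f"({self.generic})" if self.generic else "")


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.ref} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


class Structure:
    """Ordered residues with unique (chain, seq, icode) identity."""

    def __init__(self, residues: Iterable[Residue], model_id: int = 1):
        self.model_id = model_id
        self.residues: list[Residue] = list(residues)
        self._index: dict[tuple[str, int, str], Residue] = {}
        for res in self.residues:
            key = res.ref.key
            if key in self._index:
                raise ValueError(f"duplicate residue identity {key}")
            names = [(a.name, a.alt_loc) for a in res.atoms]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate atom identity in residue {res.ref}")
            self._index[key] = res

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def get_residue(self, chain: str, seq: int, icode: str = "") -> Residue:
        try:
            return self._index[(chain, seq, icode)]
        except KeyError:
            raise KeyError(f"residue {chain}/{seq}{icode} not in structure") from None

    def has_residue(self, chain: str, seq: int, icode: str = "") -> bool:
        return (chain, seq, icode) in self._index

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self.residues:
            seen.setdefault(res.ref.chain, None)
        return list(seen)

    def iter_atoms(self, chain: str | None = None, heavy_only: bool = False):
        for res in self.residues:
            if chain is not None and res.ref.chain != chain:
                continue
            for a in res.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                yield res, a

    def coords(self, chain: str | None = None, heavy_only: bool = False) -> np.ndarray:
        pts = [a.xyz for _, a in self.iter_atoms(chain, heavy_only)]
        return np.array(pts) if pts else np.empty((0, 3))

    def topology_key(self) -> tuple:
        return tuple(
            (res.ref.key, res.ref.res_name, tuple(a.name for a in res.atoms))
            for res in self.residues
        )

    def copy(self) -> "Structure":
        residues = [
            Residue(res.ref, [dataclasses.replace(a, xyz=a.xyz.copy()) for a in res.atoms])
            for res in self.residues
        ]
        return Structure(residues, model_id=self.model_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = self.copy()
        for res in out.residues:
            for a in res.atoms:
                a.xyz = rotation @ a.xyz + translation
        return out


@dataclass
class Trajectory:
    """Ordered frames over one topology; labels are typically time in ns."""

    frames: list[Structure]
    frame_labels: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        key0 = self.frames[0].topology_key()
        for i, fr in enumerate(self.frames[1:], start=2):
            if fr.topology_key() != key0:
                raise ValueError(f"frame {i} topology differs from frame 1")
        if self.frame_labels is not None and len(self.frame_labels) != len(self.frames):
            raise ValueError("frame_labels length must match number of frames")

    def __len__(self) -> int:
        return len(self.frames)

    def labels(self) -> list[float]:
        if self.frame_labels is not None:
            return list(self.frame_labels)
        return [float(i) for i in range(len(self.frames))]


# ---------------------------------------------------------------------------
# PDB I/O


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"PDB parse error at line {lineno}: record too short")
        try:
            int(line[6:11])
            int(line[22:26])
            for col in (line[30:38], line[38:46], line[46:54]):
                float(col)
        except ValueError:
            raise ValueError(
                f"PDB parse error at line {lineno}: malformed fixed-width field"
            ) from None


def _select_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by alt_loc order."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.alt_loc))
        kept.append(group[0])
    return kept


def _structure_from_gemmi(model: gemmi.Model, model_id: int) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            ref = ResidueRef(chain.name, res.seqid.num, icode, res_name=res.name)
            atoms = []
            for a in res:
                alt = a.altloc if a.altloc not in ("\x00", " ") else ""
                atoms.append(
                    AtomRecord(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name or "",
                        xyz=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        alt_loc=alt,
                        occupancy=a.occ,
                    )
                )
            identities = [(a.name, a.alt_loc) for a in atoms]
            if len(identities) != len(set(identities)):
                raise ValueError(f"duplicate atom identity in residue {ref}")
            residues.append(Residue(ref, _select_alt_locs(atoms)))
    return Structure(residues, model_id=model_id)


def read_pdb(text: str) -> Structure | Trajectory:
    """Parse PDB text; multi-model input becomes a :class:`Trajectory`.

    Alternate locations are reduced to the highest-occupancy conformer.
    Hydrogens are retained (heavy-atom searches exclude them by element).
    """
    if not any(line.startswith(("ATOM  ", "HETATM")) for line in text.splitlines()):
        raise ValueError("no ATOM/HETATM records found")
    _validate_pdb_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no models parsed from PDB text")
    frames = [_structure_from_gemmi(m, m.num) for m in st]
    if len(frames) == 1:
        return frames[0]
    return Trajectory(frames)


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}{seq:>4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}"
)


def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: element right-justified in cols 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _write_structure_lines(s: Structure, lines: list[str]) -> None:
    serial = 0
    last_chain = None
    for res in s.residues:
        if last_chain is not None and res.ref.chain != last_chain:
            lines.append("TER")
        last_chain = res.ref.chain
        for a in res.atoms:
            serial += 1
            lines.append(
                _PDB_ATOM_FMT.format(
                    serial=serial,
                    name=_format_atom_name(a.name, a.element),
                    alt=a.alt_loc or " ",
                    res=res.ref.res_name or "UNK",
                    chain=res.ref.chain[:1] or "A",
                    seq=res.ref.seq,
                    icode=res.ref.icode or " ",
                    x=a.xyz[0],
                    y=a.xyz[1],
                    z=a.xyz[2],
                    occ=a.occupancy,
                    b=0.0,
                    elem=a.element[:2],
                )
            )
    lines.append("TER")


def write_pdb(obj: Structure | Trajectory) -> str:
    """Serialize to PDB text (multi-model for trajectories)."""
    lines: list[str] = []
    if isinstance(obj, Trajectory):
        for i, frame in enumerate(obj.frames, start=1):
            lines.append(f"MODEL     {i:>4d}")
            _write_structure_lines(frame, lines)
            lines.append("ENDMDL")
    else:
        _write_structure_lines(obj, lines)
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Geometry


def distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance in Å (full precision; round only at presentation)."""
    return float(np.linalg.norm(a.xyz - b.xyz))


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N/CA/C.

    The Cβ direction makes the tetrahedral angle with both the CA→N and
    CA→C bonds, on the side given by the right-handed N,CA,C frame, at
    1.53 Å from CA.  The construction commutes with proper rigid motions.
    """
    # scalar arithmetic: this is called inside sampling hot loops
    ux, uy, uz = n[0] - ca[0], n[1] - ca[1], n[2] - ca[2]
    vx, vy, vz = c[0] - ca[0], c[1] - ca[1], c[2] - ca[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-6 or nv < 1e-6:
        raise ValueError("degenerate backbone geometry for virtual Cβ")
    ux, uy, uz = ux / nu, uy / nu, uz / nu
    vx, vy, vz = vx / nv, vy / nv, vz / nv
    wx = uy * vz - uz * vy
    wy = uz * vx - ux * vz
    wz = ux * vy - uy * vx
    nw = math.sqrt(wx * wx + wy * wy + wz * wz)
    if nw < 1e-6:
        raise ValueError("collinear backbone atoms; cannot place virtual Cβ")
    wx, wy, wz = wx / nw, wy / nw, wz / nw
    cos_t = math.cos(math.radians(TETRAHEDRAL_ANGLE))
    # d = alpha (u + v) + beta w  with  d.u = d.v = cos_t
    alpha = cos_t / (1.0 + ux * vx + uy * vy + uz * vz)
    px, py, pz = alpha * (ux + vx), alpha * (uy + vy), alpha * (uz + vz)
    beta = math.sqrt(max(1.0 - (px * px + py * py + pz * pz), 0.0))
    return np.array(
        [
            ca[0] + CA_CB_LENGTH * (px - beta * wx),
            ca[1] + CA_CB_LENGTH * (py - beta * wy),
            ca[2] + CA_CB_LENGTH * (pz - beta * wz),
        ]
    )


ANCHOR_KINDS = ("CB", "N", "CA")


def get_anchor_atom(s: Structure, r: ResidueRef | tuple, anchor: str) -> AtomRecord:
    """Resolve a restraint anchor atom; glycine Cβ is built virtually.

    ``anchor`` is one of ``CB``, ``N``, ``CA``.  For glycine (or any residue
    lacking a Cβ) the ``CB`` anchor is constructed from the backbone with
    ideal tetrahedral geometry rather than falling back to Cα, preserving
    Cβ-Cβ distance semantics.
    """
    if anchor not in ANCHOR_KINDS:
        raise ValueError(f"unknown anchor kind {anchor!r}; expected one of {ANCHOR_KINDS}")
    if isinstance(r, ResidueRef):
        chain, seq, icode = r.chain, r.seq, r.icode
    else:
        chain, seq, icode = (r + ("",))[:3]
    res = s.get_residue(chain, seq, icode)
    if anchor != "CB" or res.has_atom("CB"):
        return res.atom(anchor)
    for name in ("N", "CA", "C"):
        if not res.has_atom(name):
            raise ValueError(
                f"residue {res.ref} lacks backbone atom {name}; cannot build virtual Cβ"
            )
    xyz = virtual_cbeta(res.atom("N").xyz, res.atom("CA").xyz, res.atom("C").xyz)
    return AtomRecord(serial=0, name="CB", element="C", xyz=xyz, alt_loc="")


# ---------------------------------------------------------------------------
# Generic residue numbering


class GenericNumberMap:
    """(chain, seq) → class-B generic label plus a region/domain tag.

    CSV format: columns ``chain,seq,generic,domain`` with header.  Domains
    follow the receptor regions used in footprint work: helix I-VII, the
    extracellular loops ECL1-3, ECD and the hinge.
    """

    _HELIX_LABEL = re.compile(r"^\d+\.\d+$")

    def __init__(self, entries: dict[tuple[str, int], tuple[str, str]]):
        self.entries = dict(entries)
        # helix.position labels are injective; loop/region labels may repeat
        seen: dict[str, tuple[str, int]] = {}
        for key, (generic, _dom) in self.entries.items():
            if not self._HELIX_LABEL.match(generic):
                continue
            if generic in seen and seen[generic] != key:
                raise ValueError(f"generic label {generic!r} mapped to two residues")
            seen[generic] = key

    def __len__(self) -> int:
        return len(self.entries)

    def generic_for(self, chain: str, seq: int) -> str | None:
        ent = self.entries.get((chain, seq))
        return ent[0] if ent else None

    def domain_for(self, chain: str, seq: int) -> str | None:
        ent = self.entries.get((chain, seq))
        return ent[1] if ent else None

    @classmethod
    def from_csv(cls, path_or_buf) -> "GenericNumberMap":
        df = pd.read_csv(path_or_buf, dtype={"chain": str, "generic": str, "domain": str})
        required = {"chain", "seq", "generic", "domain"}
        if not required.issubset(df.columns):
            raise ValueError(f"numbering map CSV needs columns {sorted(required)}")
        entries = {
            (row.chain, int(row.seq)): (row.generic, row.domain)
            for row in df.itertuples()
        }
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain": c, "seq": s, "generic": g, "domain": d}
            for (c, s), (g, d) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["chain", "seq", "generic", "domain"])


def annotate(s: Structure, m: GenericNumberMap) -> tuple[Structure, list[tuple[str, int]]]:
    """Attach generic labels to mapped residues.

    Returns the annotated copy and the list of map entries that matched no
    residue (stale entries are reported, never silently dropped).
    """
    chains = set(s.chains())
    map_chains = {c for c, _ in m.entries}
    missing_chains = map_chains - chains
    if missing_chains:
        raise ValueError(f"numbering map references absent chain(s): {sorted(missing_chains)}")
    out = s.copy()
    unmatched: list[tuple[str, int]] = []
    for (chain, seq), (generic, _domain) in m.entries.items():
        if out.has_residue(chain, seq):
            res = out.get_residue(chain, seq)
            res.ref = dataclasses.replace(res.ref, generic=generic)
        else:
            unmatched.append((chain, seq))
    return out, sorted(unmatched)
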