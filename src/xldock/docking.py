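"""Desk-scale restrained flexible-peptide docking.

A reduced-representation peptide (backbone N, CA, C, O plus Cβ) with ideal
internal geometry is sampled by Metropolis Monte Carlo against a *rigid*
receptor.  Moves perturb backbone torsions (φ/ψ) or the rigid-body frame;
the score is a soft-sphere clash term plus the flat-bottom harmonic
crosslink restraints.  This is deliberately a small, reproducible sampler:
its claims are restraint logic and pose recovery on synthetic systems, not
force-field accuracy.  Receptor flexibility and all-atom refinement are out
of scope; the step budget default (5·10⁴) is a scaled-down stand-in for
production samplers that spend >10⁷ steps.

Determinism contract: a dock run is bit-reproducible for a fixed seed and
configuration on one platform; replicas derive independent streams from
the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .restraints import RestraintSet, penalty, total_restraint_energy
from .structures import (
    AtomRecord,
    Residue,
    ResidueRef,
    Structure,
    virtual_cbeta,
)

__all__ = [
    "PeptideModel",
    "DockingConfig",
    "PoseResult",
    "build_peptide",
    "energy",
    "dock",
    "complex_structure",
]

# Ideal backbone geometry (Å / degrees), Engh-Huber style values.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELICAL_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-120.0, 120.0)

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: atoms per residue in the reduced representation (Cβ kept for all
#: residue types; for glycine it is the ideal virtual Cβ).
RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c and internal coordinates.

    Scalar arithmetic on purpose: this sits in the Monte Carlo hot loop and
    3-vector numpy calls dominate the cost otherwise.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    n_norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    if n_norm < 1e-10:
        raise ValueError("collinear atoms in NeRF placement")
    inv = 1.0 / n_norm
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    c1 = -bond * math.cos(theta)
    c2 = bond * math.sin(theta) * math.cos(phi)
    c3 = bond * math.sin(theta) * math.sin(phi)
    return np.array(
        [
            c[0] + c1 * bcx + c2 * mx + c3 * nx,
            c[1] + c1 * bcy + c2 * my + c3 * ny,
            c[2] + c1 * bcz + c2 * mz + c3 * nz,
        ]
    )


@dataclass
class PeptideModel:
    """Peptide with ideal internal geometry, regenerable from torsions + frame.

    ``phi``/``psi`` are per-residue backbone torsions in degrees (φ of the
    first and ψ of the last residue are stored but geometrically unused).
    ``rotation``/``translation`` place the internally-built peptide in the
    receptor frame.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    chain: str = "L"
    start_seq: int = 1
    _local: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, float)
        self.psi = np.asarray(self.psi, float)
        n = len(self.sequence)
        if n < 1:
            raise ValueError("peptide sequence must have length >= 1")
        bad = [c for c in self.sequence if c not in AA3]
        if bad:
            raise ValueError(f"unknown residue code(s) {bad}")
        if self.phi.shape != (n,) or self.psi.shape != (n,):
            raise ValueError("phi/psi must have one entry per residue")
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)

    # -- geometry -----------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return self.n_residues * len(RESIDUE_ATOMS)

    def atom_index(self, res_index: int, atom: str) -> int:
        return res_index * len(RESIDUE_ATOMS) + RESIDUE_ATOMS.index(atom)

    def invalidate(self) -> None:
        self._local = None

    def local_coords(self) -> np.ndarray:
        """Internal-frame coordinates, rebuilt from torsions on demand."""
        if self._local is None:
            self._local = self._build_local()
        return self._local

    def _build_local(self) -> np.ndarray:
        n = self.n_residues
        # main chain first: N, CA, C per residue
        main = np.zeros((n * 3, 3))
        main[0] = (0.0, 0.0, 0.0)  # N0
        main[1] = (BOND_N_CA, 0.0, 0.0)  # CA0
        ang = math.radians(ANGLE_N_CA_C)
        main[2] = main[1] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        for i in range(1, n):
            c_prev = main[3 * i - 1]
            ca_prev = main[3 * i - 2]
            n_prev = main[3 * i - 3]
            main[3 * i] = _place_atom(
                n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, self.psi[i - 1]
            )
            main[3 * i + 1] = _place_atom(
                ca_prev, c_prev, main[3 * i], BOND_N_CA, ANGLE_C_N_CA, OMEGA
            )
            main[3 * i + 2] = _place_atom(
                c_prev, main[3 * i], main[3 * i + 1], BOND_CA_C, ANGLE_N_CA_C, self.phi[i]
            )
        coords = np.zeros((self.n_atoms, 3))
        for i in range(n):
            n_i, ca_i, c_i = main[3 * i], main[3 * i + 1], main[3 * i + 2]
            coords[self.atom_index(i, "N")] = n_i
            coords[self.atom_index(i, "CA")] = ca_i
            coords[self.atom_index(i, "C")] = c_i
            # carbonyl O: in the peptide plane, torsion ψ - 180 about N-CA-C
            if i < n - 1:
                o_torsion = self.psi[i] - 180.0
            else:
                o_torsion = 0.0  # terminal O placement is arbitrary but fixed
            coords[self.atom_index(i, "O")] = _place_atom(
                n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, o_torsion
            )
            coords[self.atom_index(i, "CB")] = virtual_cbeta(n_i, ca_i, c_i)
        return coords

    def coords(self) -> np.ndarray:
        """Coordinates in the receptor frame (x -> R x + t)."""
        return self.local_coords() @ self.rotation.T + self.translation

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def copy(self) -> "PeptideModel":
        out = replace(
            self,
            phi=self.phi.copy(),
            psi=self.psi.copy(),
            rotation=self.rotation.copy(),
            translation=self.translation.copy(),
        )
        out._local = None if self._local is None else self._local.copy()
        return out

    def to_structure(self) -> Structure:
        coords = self.coords()
        residues = []
        serial = 0
        for i, code in enumerate(self.sequence):
            ref = ResidueRef(self.chain, self.start_seq + i, res_name=AA3[code])
            atoms = []
            for name in RESIDUE_ATOMS:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=name[0],
                        xyz=coords[self.atom_index(i, name)].copy(),
                    )
                )
            residues.append(Residue(ref, atoms))
        return Structure(residues)


def build_peptide(
    sequence: str,
    initial: str = "extended",
    chain: str = "L",
    start_seq: int = 1,
) -> PeptideModel:
    """Ideal-geometry peptide in a named starting fold.

    ``helical`` sets (φ, ψ) = (-57°, -47°) — the α-helical fold adopted by
    full agonist peptides; ``extended`` sets (-120°, 120°) — the
    non-helical conformation seen for N-truncated antagonist segments.
    """
    folds = {"helical": HELICAL_PHI_PSI, "extended": EXTENDED_PHI_PSI}
    if initial not in folds:
        raise ValueError(f"unknown initial fold {initial!r}; expected one of {list(folds)}")
    phi0, psi0 = folds[initial]
    n = len(sequence)
    return PeptideModel(
        sequence=sequence,
        phi=np.full(n, phi0),
        psi=np.full(n, psi0),
        chain=chain,
        start_seq=start_seq,
    )


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class DockingConfig:
    """Monte Carlo sampler settings.

    The three-stage geometric temperature schedule and the move mix
    (40% torsion / 30% translation / 30% rotation) are sampler defaults;
    ``clash_r_min`` is a single heavy-atom soft-sphere radius.
    """

    n_steps: int = 50_000
    temperatures: tuple[float, ...] = (25.0, 5.0, 1.0, 0.1)
    torsion_sigma: float = 12.0  # degrees
    translation_sigma: float = 0.6  # Å
    rotation_sigma: float = 8.0  # degrees
    move_probabilities: tuple[float, float, float] = (0.4, 0.3, 0.3)
    clash_r_min: float = 3.0
    clash_k: float = 1.0
    n_replicas: int = 1
    seed: int = 0
    # deterministic local minimization of the best pose after sampling
    # (Monte-Carlo-minimization style); disable for a pure-MC trace
    polish: bool = True
    polish_maxiter: int = 150

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if abs(sum(self.move_probabilities) - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if not self.temperatures:
            raise ValueError("need at least one temperature stage")


@dataclass
class EnergyBreakdown:
    clash: float
    restraint: float

    @property
    def total(self) -> float:
        return self.clash + self.restraint


class _Scorer:
    """Precomputed receptor geometry + restraint anchors for fast scoring."""

    def __init__(self, receptor: Structure, peptide: PeptideModel,
                 rs: RestraintSet, cfg: DockingConfig):
        self.cfg = cfg
        rec_coords = receptor.coords(heavy_only=True)
        self.rec_tree = cKDTree(rec_coords) if rec_coords.shape[0] else None
        self.rec_coords = rec_coords
        # resolve restraint anchors: one side must live on the peptide chain
        from .structures import get_anchor_atom  # local to avoid import noise

        pep_idx = []
        rec_xyz = []
        d0 = []
        k = []
        for r in rs:
            (ca, sa, ia, aa), (cb, sb, ib, ab) = r.anchors()
            if ca == peptide.chain:
                pep_side = (sa, aa)
                rec_side = (cb, sb, ib, ab)
            elif cb == peptide.chain:
                pep_side = (sb, ab)
                rec_side = (ca, sa, ia, aa)
            else:
                raise ValueError(
                    f"restraint {r.label or r} references no peptide-chain anchor"
                )
            res_index = pep_side[0] - peptide.start_seq
            if not 0 <= res_index < peptide.n_residues:
                raise ValueError(f"restraint ligand residue {pep_side[0]} outside peptide")
            pep_idx.append(peptide.atom_index(res_index, pep_side[1]))
            rec_atom = get_anchor_atom(receptor, rec_side[:3], rec_side[3])
            rec_xyz.append(rec_atom.xyz)
            d0.append(r.d0)
            k.append(r.k)
        self.pep_anchor_idx = np.array(pep_idx, dtype=int)
        self.rec_anchor_xyz = np.array(rec_xyz) if rec_xyz else np.empty((0, 3))
        self.d0 = np.array(d0)
        self.k = np.array(k)

    def clash_energy(self, pep_coords: np.ndarray) -> float:
        if self.rec_tree is None:
            return 0.0
        r_min = self.cfg.clash_r_min
        neighbors = self.rec_tree.query_ball_point(pep_coords, r_min)
        e = 0.0
        for i, idx in enumerate(neighbors):
            if idx:
                d = np.linalg.norm(self.rec_coords[idx] - pep_coords[i], axis=1)
                gap = r_min - d
                e += float(np.sum(gap * gap))
        return self.cfg.clash_k * e

    def restraint_energy(self, pep_coords: np.ndarray) -> float:
        if self.pep_anchor_idx.size == 0:
            return 0.0
        d = np.linalg.norm(pep_coords[self.pep_anchor_idx] - self.rec_anchor_xyz, axis=1)
        excess = np.maximum(d - self.d0, 0.0)
        return float(np.sum(self.k * excess * excess))

    def breakdown(self, pep_coords: np.ndarray) -> EnergyBreakdown:
        return EnergyBreakdown(
            clash=self.clash_energy(pep_coords),
            restraint=self.restraint_energy(pep_coords),
        )


def energy(
    receptor: Structure,
    p: PeptideModel,
    rs: RestraintSet,
    cfg: DockingConfig = DockingConfig(),
) -> EnergyBreakdown:
    """Deterministic decomposed score of a pose: clash + restraint terms."""
    scorer = _Scorer(receptor, p, rs, cfg)
    return scorer.breakdown(p.coords())


def complex_structure(receptor: Structure, p: PeptideModel) -> Structure:
    """Receptor plus posed peptide as one structure."""
    residues = [Residue(res.ref, list(res.atoms)) for res in receptor.residues]
    pep = p.to_structure()
    residues.extend(pep.residues)
    return Structure(residues, model_id=receptor.model_id)


# ---------------------------------------------------------------------------
# Monte Carlo


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


@dataclass
class PoseResult:
    """Best pose of one replica with its energy decomposition and report."""

    peptide: PeptideModel
    clash_energy: float
    restraint_energy: float
    report: object  # SatisfactionReport
    acceptance_rate: float
    seed: int
    infeasible: bool
    best_trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def total_energy(self) -> float:
        return self.clash_energy + self.restraint_energy


def _polish(state: PeptideModel, scorer: _Scorer, maxiter: int) -> PeptideModel:
    """Local quasi-Newton refinement of torsions + rigid frame."""
    from scipy.optimize import minimize

    n = state.n_residues
    base = state.copy()
    R0 = base.rotation.copy()
    t0 = base.translation.copy()

    def unpack(x: np.ndarray) -> PeptideModel:
        trial = base.copy()
        trial.phi = x[:n].copy()
        trial.psi = x[n : 2 * n].copy()
        trial.invalidate()
        rotvec = x[2 * n : 2 * n + 3]
        angle = np.linalg.norm(rotvec)
        R = _rotation_matrix(rotvec / angle, angle) if angle > 1e-12 else np.eye(3)
        trial.rotation = R @ R0
        trial.translation = t0 + x[2 * n + 3 :]
        return trial

    def objective(x: np.ndarray) -> float:
        return scorer.breakdown(unpack(x).coords()).total

    x0 = np.concatenate([base.phi, base.psi, np.zeros(3), np.zeros(3)])
    res = minimize(objective, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    polished = unpack(res.x)
    if scorer.breakdown(polished.coords()).total <= scorer.breakdown(base.coords()).total:
        return polished
    return base


def _temperature_stages(cfg: DockingConfig) -> np.ndarray:
    stages = np.array_split(np.arange(cfg.n_steps), len(cfg.temperatures))
    temps = np.empty(cfg.n_steps)
    for stage, t in zip(stages, cfg.temperatures):
        temps[stage] = t
    return temps


def _run_replica(
    receptor: Structure,
    peptide: PeptideModel,
    rs: RestraintSet,
    cfg: DockingConfig,
    seed: int,
) -> PoseResult:
    rng = np.random.default_rng(seed)
    scorer = _Scorer(receptor, peptide, rs, cfg)
    state = peptide.copy()
    current = scorer.breakdown(state.coords())
    best_state = state.copy()
    best = current
    trace = [(0, current.total)]
    temps = _temperature_stages(cfg)
    # anneal move amplitudes with temperature so the cold stages refine
    scales = np.sqrt(temps / temps[0]) if cfg.n_steps else temps
    move_cdf = np.cumsum(cfg.move_probabilities)
    n_accept = 0
    for step in range(cfg.n_steps):
        u = rng.random()
        scale = scales[step]
        trial = state.copy()
        if u < move_cdf[0]:
            # torsion move: one φ or ψ of one residue
            i = rng.integers(trial.n_residues)
            delta = rng.normal(0.0, cfg.torsion_sigma * scale)
            if rng.random() < 0.5:
                trial.phi[i] += delta
            else:
                trial.psi[i] += delta
            trial.invalidate()
        elif u < move_cdf[1]:
            trial.translation = trial.translation + rng.normal(
                0.0, cfg.translation_sigma * scale, 3
            )
        else:
            axis = rng.normal(size=3)
            angle = math.radians(rng.normal(0.0, cfg.rotation_sigma * scale))
            R = _rotation_matrix(axis, angle)
            center = trial.centroid()
            trial.rotation = R @ trial.rotation
            trial.translation = R @ (trial.translation - center) + center
        cand = scorer.breakdown(trial.coords())
        dE = cand.total - current.total
        if dE <= 0 or rng.random() < math.exp(-dE / temps[step]):
            state = trial
            current = cand
            n_accept += 1
            if current.total < best.total:
                best = current
                best_state = state.copy()
                trace.append((step + 1, best.total))
    final = best_state
    if cfg.polish and cfg.n_steps > 0:
        final = _polish(final, scorer, cfg.polish_maxiter)
        best = scorer.breakdown(final.coords())
    _, report = total_restraint_energy(complex_structure(receptor, final), rs)
    return PoseResult(
        peptide=final,
        clash_energy=best.clash,
        restraint_energy=best.restraint,
        report=report,
        acceptance_rate=n_accept / cfg.n_steps if cfg.n_steps else 0.0,
        seed=seed,
        infeasible=best.restraint > 1e-9,
        best_trace=trace,
    )


def dock(
    receptor: Structure,
    peptide: PeptideModel,
    rs: RestraintSet,
    cfg: DockingConfig = DockingConfig(),
) -> list[PoseResult]:
    """Metropolis Monte Carlo docking; returns per-replica best poses.

    Results are ranked by total energy.  Mutually unsatisfiable restraints
    are not an error: the best pose simply keeps residual restraint energy
    and is flagged ``infeasible``.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicas)
    results = []
    for i, ss in enumerate(seeds):
        replica_seed = int(ss.generate_state(1)[0] % (2**31))
        results.append(_run_replica(receptor, peptide, rs, cfg, replica_seed))
    return sorted(results, key=lambda r: r.total_energy)
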