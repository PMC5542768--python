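"""Ground-truthed toy systems for the crosslink-to-structure pipeline.

The generator builds what the experimental pipeline assumes: a
transmembrane-like bundle of ideal α-helices on a ring (single receptor
chain R), a peptide planted in the central pocket (chain L) with a known
pose, photo-scan intensity tables that decay with distance, pair-wise hit
tables consistent with each crosslinker's reach, and smoothly perturbed
trajectories with closed-form distance truth.

Truth is definitionally consistent with the validators: a residue is
photo-proximal iff its Cβ lies within the probe radius (9 Å) of any
peptide heavy atom, and a residue pair is a pair-wise truth entry iff its
anchor distance is within the crosslinker's d0.  Real scans differ in ways
the generator does not emulate (expression variation, blot saturation,
reactivity differences between sites); the intensity law here is a simple
exponential distance decay with multiplicative lognormal noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .docking import PeptideModel, build_peptide, complex_structure
from .footprints import IntensityTable
from .restraints import CrosslinkerSpec, PairwiseHit, default_registry
from .structures import (
    GenericNumberMap,
    ResidueRef,
    Structure,
    Trajectory,
    get_anchor_atom,
)

__all__ = [
    "BundleConfig",
    "NoiseModel",
    "ComplexTruth",
    "make_bundle",
    "bundle_numbering_map",
    "plant_peptide",
    "simulate_photo_scan",
    "simulate_pairwise",
    "perturb_trajectory",
    "TrajectoryTruth",
]

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]

#: minimum helix-axis separation (Å) below which the ring geometry clashes
MIN_HELIX_SEPARATION = 7.5


@dataclass(frozen=True)
class BundleConfig:
    """Geometry of the synthetic receptor bundle."""

    n_helices: int = 7
    helix_length: int = 25
    ring_radius: float = 11.0
    tilt_deg: float = 0.0
    chain: str = "R"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.ring_radius <= 0:
            raise ValueError("ring radius must be positive")
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")


def _axis_align_rotation(axis_from: np.ndarray, axis_to: np.ndarray) -> np.ndarray:
    a = axis_from / np.linalg.norm(axis_from)
    b = axis_to / np.linalg.norm(axis_to)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1 / (1 + c))


def _principal_axis(ca_coords: np.ndarray) -> np.ndarray:
    centered = ca_coords - ca_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient from first to last residue
    if axis @ (ca_coords[-1] - ca_coords[0]) < 0:
        axis = -axis
    return axis


def _posed_helix(length: int, chain: str, start_seq: int) -> PeptideModel:
    helix = build_peptide("A" * length, initial="helical", chain=chain, start_seq=start_seq)
    return helix


def make_bundle(cfg: BundleConfig = BundleConfig()) -> Structure:
    """Ideal poly-alanine α-helical bundle on a ring, single chain.

    Helices alternate up/down (antiparallel), each aligned to the membrane
    normal (z) up to ``tilt_deg``, with consecutive residue numbering and a
    2-residue numbering gap between helices.  Deterministic per config.
    """
    if cfg.n_helices > 1:
        separation = 2 * cfg.ring_radius * np.sin(np.pi / cfg.n_helices)
        if separation < MIN_HELIX_SEPARATION:
            raise ValueError(
                f"helices would overlap: axis separation {separation:.1f} Å "
                f"< {MIN_HELIX_SEPARATION} Å; increase ring_radius"
            )
    residues = []
    seq = 1
    rng = np.random.default_rng(cfg.seed)  # reserved for future jitter; keeps contract
    for h in range(cfg.n_helices):
        helix = _posed_helix(cfg.helix_length, cfg.chain, seq)
        coords = helix.coords()
        ca = np.array(
            [coords[helix.atom_index(i, "CA")] for i in range(cfg.helix_length)]
        )
        axis = _principal_axis(ca)
        direction = np.array([0.0, 0.0, 1.0 if h % 2 == 0 else -1.0])
        R = _axis_align_rotation(axis, direction)
        if cfg.tilt_deg:
            tilt = np.radians(cfg.tilt_deg)
            tilt_axis = np.array([1.0, 0.0, 0.0])
            K = np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float)
            R_tilt = np.eye(3) + np.sin(tilt) * K + (1 - np.cos(tilt)) * (K @ K)
            R = R_tilt @ R
        angle = 2 * np.pi * h / cfg.n_helices
        center = cfg.ring_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        helix.rotation = R
        helix.translation = np.zeros(3)
        helix.translation = center - helix.centroid()
        st = helix.to_structure()
        residues.extend(st.residues)
        seq += cfg.helix_length + 2  # numbering gap marks the inter-helix loop
    return Structure(residues)


def bundle_numbering_map(cfg: BundleConfig = BundleConfig()) -> GenericNumberMap:
    """Helix-position generic labels (h.50 at the helix midpoint)."""
    entries = {}
    seq = 1
    for h in range(cfg.n_helices):
        mid = cfg.helix_length // 2
        for i in range(cfg.helix_length):
            label = f"{h + 1}.{50 + i - mid}"
            domain = f"helix {ROMAN[h]}"
            entries[(cfg.chain, seq + i)] = (label, domain)
        seq += cfg.helix_length + 2
    return GenericNumberMap(entries)


@dataclass
class ComplexTruth:
    """Ground truth for one planted complex, recomputable from coordinates."""

    peptide: PeptideModel
    photo_radius: float
    photo_truth: set[tuple[str, int]]  # receptor residues proximal to the peptide
    pair_truth: dict[str, list[tuple[int, tuple[str, int]]]]  # crosslinker -> pairs
    seed: int = 0

    def pair_count(self) -> int:
        return sum(len(v) for v in self.pair_truth.values())


def _photo_truth(
    receptor: Structure, complex_st: Structure, ligand_chain: str, radius: float
) -> set[tuple[str, int]]:
    ligand_heavy = complex_st.coords(chain=ligand_chain, heavy_only=True)
    truth = set()
    for res in receptor:
        cb = get_anchor_atom(complex_st, res.ref, "CB")
        if np.min(np.linalg.norm(ligand_heavy - cb.xyz, axis=1)) <= radius:
            truth.add((res.ref.chain, res.ref.seq))
    return truth


def _pair_truth(
    receptor: Structure,
    peptide: PeptideModel,
    complex_st: Structure,
    specs: dict[str, CrosslinkerSpec],
) -> dict[str, list[tuple[int, tuple[str, int]]]]:
    out: dict[str, list[tuple[int, tuple[str, int]]]] = {}
    pep_coords = peptide.coords()
    for name, spec in specs.items():
        if name == "AZI_PHOTO":
            continue  # photo probe is validation-only, not a pair-wise table
        pairs = []
        if spec.ligand_anchor == "N":
            ligand_positions = [0]  # N-terminal chemistry only
        else:
            ligand_positions = range(peptide.n_residues)
        for i in ligand_positions:
            anchor_xyz = pep_coords[peptide.atom_index(i, spec.ligand_anchor)]
            for res in receptor:
                rec_atom = get_anchor_atom(complex_st, res.ref, spec.receptor_anchor)
                if np.linalg.norm(anchor_xyz - rec_atom.xyz) <= spec.d0:
                    pairs.append(
                        (peptide.start_seq + i, (res.ref.chain, res.ref.seq))
                    )
        out[name] = pairs
    return out


def plant_peptide(
    bundle: Structure,
    sequence: str,
    pose: str = "helical",
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    specs: dict[str, CrosslinkerSpec] | None = None,
    photo_radius: float = 9.0,
    chain: str = "L",
    clash_tolerance: float = 2.5,
) -> tuple[Structure, ComplexTruth]:
    """Place a peptide in the bundle pocket and record ground truth.

    ``pose`` is one of ``helical``, ``extended``, ``kinked`` (helical with
    a short non-helical loop at the middle two residues — the agonist-style
    bend).  Default frame: peptide axis along z, centred in the pore.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    specs = specs if specs is not None else default_registry()
    if pose in ("helical", "extended"):
        peptide = build_peptide(sequence, initial=pose, chain=chain)
    elif pose == "kinked":
        peptide = build_peptide(sequence, initial="helical", chain=chain)
        mid = peptide.n_residues // 2
        for i in (mid - 1, mid):
            if 0 <= i < peptide.n_residues:
                peptide.phi[i], peptide.psi[i] = -90.0, 0.0
        peptide.invalidate()
    else:
        raise ValueError(f"unknown pose {pose!r}")
    coords = peptide.coords()
    ca = np.array([coords[peptide.atom_index(i, "CA")] for i in range(peptide.n_residues)])
    if len(ca) >= 2:
        R_align = _axis_align_rotation(_principal_axis(ca), np.array([0.0, 0.0, 1.0]))
    else:
        R_align = np.eye(3)
    peptide.rotation = R_align if rotation is None else np.asarray(rotation, float)
    bundle_centroid = bundle.coords().mean(axis=0)
    peptide.translation = np.zeros(3)
    if translation is None:
        peptide.translation = bundle_centroid - peptide.centroid()
    else:
        peptide.translation = np.asarray(translation, float)
    complex_st = complex_structure(bundle, peptide)
    rec_heavy = bundle.coords(heavy_only=True)
    pep_heavy = peptide.coords()
    dmin = np.min(
        np.linalg.norm(rec_heavy[None, :, :] - pep_heavy[:, None, :], axis=2)
    )
    if dmin < clash_tolerance:
        raise ValueError(
            f"planted peptide clashes with receptor (min distance {dmin:.2f} Å "
            f"< {clash_tolerance} Å); adjust the frame"
        )
    truth = ComplexTruth(
        peptide=peptide,
        photo_radius=photo_radius,
        photo_truth=_photo_truth(bundle, complex_st, chain, photo_radius),
        pair_truth=_pair_truth(bundle, peptide, complex_st, specs),
    )
    return complex_st, truth


@dataclass(frozen=True)
class NoiseModel:
    """Distance-decay intensity law with multiplicative lognormal noise.

    In-reach residues report I = i_max · exp(−d/decay_length); everything
    else sits at ``background``.  ``sigma`` is the lognormal spread of the
    multiplicative noise (0 = noiseless).
    """

    i_max: float = 100.0
    background: float = 1.0
    decay_length: float = 4.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # i_max == background is a degenerate boundary (warned at scan time)
        if not self.i_max >= self.background >= 0:
            raise ValueError("need i_max >= background >= 0")
        if self.decay_length <= 0 or self.sigma < 0:
            raise ValueError("decay_length must be positive and sigma non-negative")


def simulate_photo_scan(
    complex_st: Structure,
    truth: ComplexTruth,
    noise: NoiseModel = NoiseModel(),
    ligand_id: str = "peptide",
    receptor_chain: str = "R",
    ligand_chain: str = "L",
) -> IntensityTable:
    """Band-intensity table for a positional photo-crosslink scan."""
    if noise.i_max == noise.background:
        warnings.warn("degenerate noise model: i_max equals background")
    rng = np.random.default_rng(noise.seed)
    ligand_heavy = complex_st.coords(chain=ligand_chain, heavy_only=True)
    rows = []
    for res in complex_st:
        if res.ref.chain != receptor_chain:
            continue
        cb = get_anchor_atom(complex_st, res.ref, "CB")
        d = float(np.min(np.linalg.norm(ligand_heavy - cb.xyz, axis=1)))
        if (res.ref.chain, res.ref.seq) in truth.photo_truth:
            intensity = noise.i_max * np.exp(-d / noise.decay_length)
        else:
            intensity = noise.background
        if noise.sigma > 0:
            intensity *= float(np.exp(rng.normal(0.0, noise.sigma)))
        rows.append(
            {"ligand": ligand_id, "chain": res.ref.chain, "seq": res.ref.seq, "intensity": intensity}
        )
    return IntensityTable(pd.DataFrame(rows), provenance="synthetic photo scan")


def simulate_pairwise(
    complex_st: Structure,
    truth: ComplexTruth,
    specs: dict[str, CrosslinkerSpec] | None = None,
    dropout: float = 0.0,
    seed: int = 0,
    ligand_id: str = "peptide",
    ligand_chain: str = "L",
) -> list[PairwiseHit]:
    """Pair-wise hit table: exactly the truth pairs, minus seeded dropout."""
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must be in [0, 1]")
    specs = specs if specs is not None else default_registry()
    rng = np.random.default_rng(seed)
    hits = []
    for name in sorted(truth.pair_truth):
        if name not in specs:
            raise KeyError(f"truth references unregistered crosslinker {name!r}")
        for lig_seq, (rec_chain, rec_seq) in truth.pair_truth[name]:
            if dropout > 0 and rng.random() < dropout:
                continue
            hits.append(
                PairwiseHit(
                    ligand_id=ligand_id,
                    ligand_residue=ResidueRef(ligand_chain, lig_seq),
                    receptor_residue=ResidueRef(rec_chain, rec_seq),
                    crosslinker=name,
                )
            )
    return hits


@dataclass
class TrajectoryTruth:
    """Analytic record of the rigid ligand motion applied per frame."""

    mode: str
    offsets: np.ndarray  # (n_frames, 3) displacement of the moved selection

    def expected_distance(self, moved_xyz: np.ndarray, fixed_xyz: np.ndarray) -> np.ndarray:
        """Closed-form |moved + offset_k − fixed| for all frames."""
        return np.linalg.norm(moved_xyz[None, :] + self.offsets - fixed_xyz[None, :], axis=1)


def perturb_trajectory(
    complex_st: Structure,
    n_frames: int,
    amplitude: float,
    mode: str = "global_sway",
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
    moved_chain: str = "L",
    loop_residue: tuple[str, int] | None = None,
    seed: int = 0,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Deterministic smooth perturbation of the planted complex.

    ``global_sway`` translates the ligand chain rigidly along ``axis``,
    linearly from 0 to ``amplitude`` — the rigid-body analogue of a domain
    swaying relative to the bundle, with closed-form distance truth.
    ``local_loop`` instead translates one receptor residue (``loop_residue``)
    along ``axis``, emulating a flexible loop approaching the ligand.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    u = np.asarray(axis, float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    u = u / norm
    steps = np.zeros(n_frames) if n_frames == 1 else np.linspace(0.0, 1.0, n_frames)
    offsets = amplitude * steps[:, None] * u[None, :]
    frames = []
    for k in range(n_frames):
        frame = complex_st.copy()
        frame.model_id = k + 1
        for res in frame:
            if mode == "global_sway":
                move = res.ref.chain == moved_chain
            elif mode == "local_loop":
                if loop_residue is None:
                    raise ValueError("local_loop mode needs loop_residue=(chain, seq)")
                move = (res.ref.chain, res.ref.seq) == loop_residue
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if move:
                for a in res.atoms:
                    a.xyz = a.xyz + offsets[k]
        frames.append(frame)
    return Trajectory(frames, frame_labels=list(map(float, range(n_frames)))), TrajectoryTruth(
        mode=mode, offsets=offsets
    )
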