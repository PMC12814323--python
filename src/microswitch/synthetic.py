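"""Ground-truth-labeled synthetic ensembles.

Emulates the statistical structure the downstream analysis assumes: each
ensemble (binding state) occupies its own region of backbone-conformation
space, contains 4-6 metastable microstates visited by a Markov chain, and
carries side chains whose rotamer state is coupled to the hidden microstate
with tunable strength kappa. Uncoupled side chains serve as negative
controls.

Geometry is a toy: residues on an idealized alpha-helical backbone, with
ensemble and microstate displacements applied to a contiguous C-terminal
segment (a "TM6-like" rigid tilt), so the leading principal component has
an interpretable rigid-displacement meaning. No force field, solvent or
membrane is modelled.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._geom import place_atom
from .trajio import Replica, Topology, TrajectoryEnsemble, write_ensemble
from .rotamers import RotamerScheme, build_default_scheme

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "DihedralFixture",
    "InvalidSpecError",
    "generate_topology",
    "simulate_ensemble",
    "dihedral_only_fixture",
    "write_dataset",
]


class InvalidSpecError(ValueError):
    """The synthetic spec violates a structural invariant."""


# Default residue-name pattern: mixes chi2-bearing probes (LEU, TRP), a
# chi1-only type (VAL), and rotamer-less residues (ALA, GLY) that the
# coupling scan must exclude.
_NAME_CYCLE = ("VAL", "LEU", "TRP", "ALA", "VAL", "LEU", "SER", "GLY")

# Internal-coordinate recipes for toy side chains: atom, frame triple,
# bond length (A), bond angle (deg), torsion ("chi1"/"chi2" or a fixed
# offset relative to them, or an absolute number for CB).
_SIDE_CHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, object]]] = {
    "ALA": [("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0)],
    "VAL": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0),
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, ("chi1", 120.0)),
    ],
    "LEU": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0),
        ("CG", ("N", "CA", "CB"), 1.53, 110.5, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.53, 110.5, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.53, 110.5, ("chi2", 120.0)),
    ],
    "TRP": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0),
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, "chi2"),
    ],
    "SER": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0),
        ("OG", ("N", "CA", "CB"), 1.42, 110.8, "chi1"),
    ],
    "THR": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0),
        ("OG1", ("N", "CA", "CB"), 1.42, 110.8, "chi1"),
    ],
    "PHE": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.0),
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, "chi2"),
    ],
    "GLY": [],
    "PRO": [("CB", ("C", "N", "CA"), 1.53, 103.0, -120.0)],
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study design.

    Defaults mirror a 12-trajectory study (4 ensembles x 3 replicas) at
    desk scale, with 4-6 microstates per ensemble.
    """

    n_ensembles: int = 4
    replicas_per_ensemble: int = 3
    n_frames: int = 20_000
    frame_dt: float = 1.0
    n_residues: int = 10
    residue_names: list[str] | None = None
    n_microstates: int | None = None  # None -> draw from {4,5,6} per ensemble
    ensemble_offset_scale: float = 6.0  # A, separation of ensemble regions
    microstate_offset_scale: float = 2.0  # A, separation of microstates
    ensemble_offsets: np.ndarray | None = None  # (n_ensembles, 3)
    microstate_offsets: np.ndarray | None = None  # (max_microstates, 3)
    transition_matrix: np.ndarray | None = None  # row-stochastic, requires int n_microstates
    stay_probability: float = 0.98  # used when transition_matrix is None
    noise_sigma: float = 0.5  # A, isotropic positional noise
    coupled_residues: list[tuple[int, float]] = field(default_factory=list)
    rotamer_emission: dict[int, np.ndarray] | None = None  # residue -> (K, n_states)
    chi_jitter_deg: float = 15.0  # wrapped-Gaussian spread about the bin center
    segment_fraction: float = 0.35  # trailing fraction of residues carrying offsets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise InvalidSpecError("n_residues must be >= 4")
        if self.n_ensembles < 1 or self.replicas_per_ensemble < 1 or self.n_frames < 1:
            raise InvalidSpecError("counts must be positive")
        if self.residue_names is None:
            self.residue_names = [
                _NAME_CYCLE[i % len(_NAME_CYCLE)] for i in range(self.n_residues)
            ]
        if len(self.residue_names) != self.n_residues:
            raise InvalidSpecError("residue_names length must equal n_residues")
        for name in self.residue_names:
            if name not in _SIDE_CHAINS:
                raise InvalidSpecError(f"unsupported toy residue type {name!r}")
        if self.n_microstates is not None and not (1 <= self.n_microstates <= 12):
            raise InvalidSpecError("n_microstates must be within [1, 12]")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if self.n_microstates is None:
                raise InvalidSpecError("transition_matrix requires explicit n_microstates")
            if t.shape != (self.n_microstates, self.n_microstates):
                raise InvalidSpecError("transition_matrix shape mismatch")
            if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
                raise InvalidSpecError("transition_matrix must be row-stochastic")
            self.transition_matrix = t
        for res, kappa in self.coupled_residues:
            if not 0 <= res < self.n_residues:
                raise InvalidSpecError(f"coupled residue index {res} out of range")
            if not 0.0 <= kappa <= 1.0:
                raise InvalidSpecError("coupling strength kappa must lie in [0, 1]")
            if self.residue_names[res] in ("ALA", "GLY", "PRO"):
                raise InvalidSpecError(
                    f"residue {res} ({self.residue_names[res]}) has no rotameric states"
                )

    def microstate_counts(self, rng: np.random.Generator) -> list[int]:
        if self.n_microstates is not None:
            return [self.n_microstates] * self.n_ensembles
        return [int(k) for k in rng.choice([4, 5, 6], size=self.n_ensembles)]

    def chain_matrix(self, k: int) -> np.ndarray:
        if self.transition_matrix is not None:
            return self.transition_matrix
        if k == 1:
            return np.ones((1, 1))
        t = np.full((k, k), (1.0 - self.stay_probability) / (k - 1))
        np.fill_diagonal(t, self.stay_probability)
        return t


@dataclass
class GroundTruth:
    """Hidden state labels behind a simulated ensemble."""

    microstate_series: list[np.ndarray]  # per replica
    rotamer_series: list[dict[int, np.ndarray]]  # per replica: residue -> states
    ensemble_labels: list[str]  # per replica

    def __post_init__(self) -> None:
        if not (
            len(self.microstate_series)
            == len(self.rotamer_series)
            == len(self.ensemble_labels)
        ):
            raise InvalidSpecError("ground-truth lists must be replica-aligned")


@dataclass
class DihedralFixture:
    """Coordinate-free draw from the same statistical model (fast tests)."""

    microstates: np.ndarray  # concatenated over replicas of one ensemble
    chi1: dict[int, np.ndarray]  # residue -> degrees
    chi2: dict[int, np.ndarray]  # residue -> degrees (chi2-bearing residues only)
    rotamer_states: dict[int, np.ndarray]  # residue -> emitted state index


# ---------------------------------------------------------------------------
# Topology and backbone geometry


def _helix_backbone(n_residues: int) -> np.ndarray:
    """Idealized alpha-helix N/CA/C coordinates, shape (n_residues, 3, 3)."""
    rise, turn = 1.5, np.radians(100.0)
    out = np.empty((n_residues, 3, 3))
    for i in range(n_residues):
        base = i * turn
        z = i * rise
        # N, CA, C at staggered phases/radii around the helix axis
        for j, (radius, dphi, dz) in enumerate(
            [(1.65, -0.50, -0.95), (2.30, 0.00, 0.00), (1.65, 0.45, 1.05)]
        ):
            phi = base + dphi
            out[i, j] = (radius * np.cos(phi), radius * np.sin(phi), z + dz)
    return out


def _topology_atoms(spec: SyntheticSpec) -> tuple[Topology, list[list[tuple]]]:
    """Build the Topology plus per-residue side-chain recipes."""
    atom_names: list[str] = []
    atom_res: list[int] = []
    recipes: list[list[tuple]] = []
    for i, rname in enumerate(spec.residue_names):
        for bb in ("N", "CA", "C"):
            atom_names.append(bb)
            atom_res.append(i)
        recipe = _SIDE_CHAINS[rname]
        recipes.append(recipe)
        for entry in recipe:
            atom_names.append(entry[0])
            atom_res.append(i)
    top = Topology(
        residue_names=list(spec.residue_names),
        residue_ids=list(range(1, spec.n_residues + 1)),
        atom_names=atom_names,
        atom_residue_index=np.asarray(atom_res),
    )
    return top, recipes


def generate_topology(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Topology plus reference coordinates of the idealized structure.

    Every residue carries N, CA, C; chi-bearing residues additionally carry
    the atoms of their defined chi1/chi2 quadruples. Side chains in the
    reference structure sit at chi = 180 (trans).
    """
    top, recipes = _topology_atoms(spec)
    bb = _helix_backbone(spec.n_residues)
    coords = np.zeros((top.n_atoms, 3))
    cursor = 0
    for i in range(spec.n_residues):
        coords[cursor : cursor + 3] = bb[i]
        placed = {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2]}
        cursor += 3
        for name, frame, bond, angle, torsion in recipes[i]:
            if isinstance(torsion, str):
                tor = 180.0
            elif isinstance(torsion, tuple):
                tor = 180.0 + torsion[1]
            else:
                tor = float(torsion)
            a, b, c = (placed[x] for x in frame)
            placed[name] = place_atom(a, b, c, bond, angle, tor)
            coords[cursor] = placed[name]
            cursor += 1
    return top, coords


# ---------------------------------------------------------------------------
# Rotamer emission model


def _bin_centers(scheme: RotamerScheme, resname: str) -> tuple[np.ndarray, np.ndarray | None]:
    spec = scheme.residue_schemes[resname]
    centers1 = np.asarray(spec.angles[0].centers)
    centers2 = np.asarray(spec.angles[1].centers) if len(spec.angles) > 1 else None
    return centers1, centers2


def _emission_matrix(
    spec: SyntheticSpec, residue: int, n_states: int, k_micro: int
) -> np.ndarray:
    """Row-stochastic (microstate -> rotamer state) emission table.

    kappa interpolates between a microstate-independent uniform emission
    (kappa=0) and a deterministic map state = microstate mod n_states
    (kappa=1).
    """
    if spec.rotamer_emission and residue in spec.rotamer_emission:
        em = np.asarray(spec.rotamer_emission[residue], dtype=float)
        if em.shape != (k_micro, n_states):
            raise InvalidSpecError(f"rotamer_emission for residue {residue}: bad shape")
        if np.any(em < 0) or np.any(np.abs(em.sum(axis=1) - 1.0) > 1e-12):
            raise InvalidSpecError(f"rotamer_emission for residue {residue}: not stochastic")
        return em
    kappa = dict(spec.coupled_residues).get(residue, 0.0)
    base = np.full((k_micro, n_states), 1.0 / n_states)
    det = np.zeros((k_micro, n_states))
    det[np.arange(k_micro), np.arange(k_micro) % n_states] = 1.0
    return (1.0 - kappa) * base + kappa * det


def _sample_categorical_rows(
    rng: np.random.Generator, table: np.ndarray, rows: np.ndarray
) -> np.ndarray:
    """Draw one categorical sample per frame from table[rows[f]]."""
    cdf = np.cumsum(table, axis=1)
    u = rng.random(rows.shape[0])
    return (u[:, None] > cdf[rows]).sum(axis=1)


def _wrap(angles: np.ndarray) -> np.ndarray:
    out = np.mod(angles + 180.0, 360.0) - 180.0
    return np.where(out == -180.0, 180.0, out)


def _chi_from_states(
    rng: np.random.Generator,
    states: np.ndarray,
    centers1: np.ndarray,
    centers2: np.ndarray | None,
    jitter: float,
) -> tuple[np.ndarray, np.ndarray | None]:
    n2 = 1 if centers2 is None else len(centers2)
    i1, i2 = states // n2, states % n2
    chi1 = _wrap(centers1[i1] + rng.normal(0.0, jitter, size=states.shape))
    chi2 = None
    if centers2 is not None:
        chi2 = _wrap(centers2[i2] + rng.normal(0.0, jitter, size=states.shape))
    return chi1, chi2


def _simulate_chain(
    rng: np.random.Generator, t: np.ndarray, n_frames: int, start: int | None = None
) -> np.ndarray:
    k = t.shape[0]
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = rng.integers(k) if start is None else start
    cdf = np.cumsum(t, axis=1)
    u = rng.random(n_frames - 1)
    for f in range(1, n_frames):
        states[f] = np.searchsorted(cdf[states[f - 1]], u[f - 1], side="right")
    return states


# ---------------------------------------------------------------------------
# Main simulation


def _default_directions(n: int, phase: float = 0.0) -> np.ndarray:
    """Unit displacement directions with near-uniform pairwise separation.

    Octahedron vertices cover up to 6 states; icosahedron vertices cover
    up to 12. A planar polygon is deliberately avoided: after rigid-body
    superposition a planar arrangement leaves some state pairs much
    closer than others.
    """
    octa = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1]],
        dtype=float,
    )
    if n <= 6:
        dirs = octa[:n]
    else:
        g = (1.0 + np.sqrt(5.0)) / 2.0
        ico = np.array(
            [
                [0, 1, g], [0, -1, g], [0, 1, -g], [0, -1, -g],
                [1, g, 0], [-1, g, 0], [1, -g, 0], [-1, -g, 0],
                [g, 0, 1], [g, 0, -1], [-g, 0, 1], [-g, 0, -1],
            ],
            dtype=float,
        )
        dirs = ico[:n] / np.linalg.norm(ico[0])
    if phase:
        c, s = np.cos(phase), np.sin(phase)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        dirs = dirs @ rot.T
    return dirs


def simulate_ensemble(
    spec: SyntheticSpec,
    start_state: int | None = None,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Simulate all ensembles of the study design.

    Per replica: a hidden microstate path is drawn from the Markov chain;
    backbone coordinates are the idealized helix plus the ensemble offset
    and the microstate offset (both applied to the trailing "TM6-like"
    segment) plus isotropic Gaussian noise; side-chain atoms are then
    placed by internal coordinates so the chi angles realize the emitted
    rotamer state (bin center + wrapped-Gaussian jitter).

    Identical specs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = build_default_scheme()
    top, recipes = _topology_atoms(spec)
    bb = _helix_backbone(spec.n_residues)

    k_per_ens = spec.microstate_counts(rng)
    k_max = max(k_per_ens)
    if spec.ensemble_offsets is not None:
        ens_off = np.asarray(spec.ensemble_offsets, dtype=float)
    else:
        ens_off = spec.ensemble_offset_scale * _default_directions(
            spec.n_ensembles, phase=np.pi / 7.0
        )
    if spec.microstate_offsets is not None:
        micro_off = np.asarray(spec.microstate_offsets, dtype=float)
    else:
        micro_off = spec.microstate_offset_scale * _default_directions(k_max)

    seg_start = int(round(spec.n_residues * (1.0 - spec.segment_fraction)))
    seg_mask = np.zeros(spec.n_residues, dtype=bool)
    seg_mask[seg_start:] = True

    chi_bearing = [
        i
        for i, name in enumerate(spec.residue_names)
        if name in scheme.residue_schemes
    ]

    replicas: list[Replica] = []
    gt_micro: list[np.ndarray] = []
    gt_rot: list[dict[int, np.ndarray]] = []
    gt_labels: list[str] = []

    for e in range(spec.n_ensembles):
        label = f"ens{e}"
        k = k_per_ens[e]
        t = spec.chain_matrix(k)
        for r in range(spec.replicas_per_ensemble):
            micro = _simulate_chain(rng, t, spec.n_frames, start=start_state)
            coords = np.empty((spec.n_frames, top.n_atoms, 3))

            # backbone: helix + segment displacements + noise
            cursor = 0
            bb_noise = rng.normal(0.0, spec.noise_sigma, size=(spec.n_frames, spec.n_residues, 3, 3))
            offsets = ens_off[e][None, :] + micro_off[micro]  # (F, 3)
            bb_frames = np.broadcast_to(bb, (spec.n_frames, *bb.shape)).copy()
            bb_frames += bb_noise
            bb_frames[:, seg_mask, :, :] += offsets[:, None, None, :]

            # rotamer states per chi-bearing residue
            rot: dict[int, np.ndarray] = {}
            chi_targets: dict[int, tuple[np.ndarray, np.ndarray | None]] = {}
            for res in chi_bearing:
                rname = spec.residue_names[res]
                n_states = scheme.count(rname)
                em = _emission_matrix(spec, res, n_states, k)
                states = _sample_categorical_rows(rng, em, micro)
                rot[res] = states
                c1, c2 = _bin_centers(scheme, rname)
                chi_targets[res] = _chi_from_states(rng, states, c1, c2, spec.chi_jitter_deg)

            # assemble full coordinates frame-wise (vectorized over frames)
            for i in range(spec.n_residues):
                placed = {
                    "N": bb_frames[:, i, 0],
                    "CA": bb_frames[:, i, 1],
                    "C": bb_frames[:, i, 2],
                }
                coords[:, cursor : cursor + 3] = bb_frames[:, i]
                cursor += 3
                if recipes[i]:
                    tgt = chi_targets.get(i)
                    for name, frame, bond, angle, torsion in recipes[i]:
                        if isinstance(torsion, str):
                            tor = tgt[0] if torsion == "chi1" else tgt[1]
                        elif isinstance(torsion, tuple):
                            base_t = tgt[0] if torsion[0] == "chi1" else tgt[1]
                            tor = base_t + torsion[1]
                        else:
                            tor = float(torsion)
                        a, b, c = (placed[x] for x in frame)
                        placed[name] = place_atom(a, b, c, bond, angle, tor)
                        coords[:, cursor] = placed[name]
                        cursor += 1

            replicas.append(
                Replica(label=label, coords=coords, frame_dt=spec.frame_dt, replica_id=r)
            )
            gt_micro.append(micro)
            gt_rot.append(rot)
            gt_labels.append(label)

    ensemble = TrajectoryEnsemble(topology=top, replicas=replicas)
    truth = GroundTruth(
        microstate_series=gt_micro, rotamer_series=gt_rot, ensemble_labels=gt_labels
    )
    return ensemble, truth


def dihedral_only_fixture(spec: SyntheticSpec, ensemble_index: int = 0) -> DihedralFixture:
    """Fast coordinate-free draw: hidden states and chi angles only.

    Same statistical model as ``simulate_ensemble`` (Markov microstates,
    kappa-coupled rotamer emission, jittered bin-center chi angles) but
    skipping all geometry; replicas of one ensemble are concatenated.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = build_default_scheme()
    k = spec.microstate_counts(rng)[ensemble_index]
    t = spec.chain_matrix(k)
    chi_bearing = [
        i for i, n in enumerate(spec.residue_names) if n in scheme.residue_schemes
    ]

    micro_parts, rot_parts = [], {r: [] for r in chi_bearing}
    chi1_parts = {r: [] for r in chi_bearing}
    chi2_parts = {r: [] for r in chi_bearing}
    for _ in range(spec.replicas_per_ensemble):
        micro = _simulate_chain(rng, t, spec.n_frames)
        micro_parts.append(micro)
        for res in chi_bearing:
            rname = spec.residue_names[res]
            em = _emission_matrix(spec, res, scheme.count(rname), k)
            states = _sample_categorical_rows(rng, em, micro)
            rot_parts[res].append(states)
            c1, c2 = _bin_centers(scheme, rname)
            chi1, chi2 = _chi_from_states(rng, states, c1, c2, spec.chi_jitter_deg)
            chi1_parts[res].append(chi1)
            if chi2 is not None:
                chi2_parts[res].append(chi2)

    return DihedralFixture(
        microstates=np.concatenate(micro_parts),
        chi1={r: np.concatenate(v) for r, v in chi1_parts.items()},
        chi2={r: np.concatenate(v) for r, v in chi2_parts.items() if v},
        rotamer_states={r: np.concatenate(v) for r, v in rot_parts.items()},
    )


# ---------------------------------------------------------------------------
# Persistence


def write_dataset(spec: SyntheticSpec, outdir: str | os.PathLike) -> dict[str, str]:
    """Simulate and persist a full dataset.

    Writes the topology PDB, one DCD per replica, per-replica ground-truth
    CSV tables (frame, hidden microstate, true rotamer state per coupled
    residue) and a JSON echo of the spec.
    """
    ensemble, truth = simulate_ensemble(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = write_ensemble(ensemble, outdir, trajectory_format="dcd")

    import pandas as pd

    for i, rep in enumerate(ensemble.replicas):
        df = pd.DataFrame({"frame": np.arange(rep.coords.shape[0])})
        df["microstate"] = truth.microstate_series[i]
        for res, states in sorted(truth.rotamer_series[i].items()):
            df[f"rotamer_res{res}"] = states
        path = os.path.join(outdir, f"truth_{rep.label}_{rep.replica_id}.csv")
        df.to_csv(path, index=False)
        paths[f"truth:{rep.label}:{rep.replica_id}"] = path

    echo = dataclasses.asdict(spec)
    for key, val in echo.items():
        if isinstance(val, np.ndarray):
            echo[key] = val.tolist()
    if echo.get("rotamer_emission"):
        echo["rotamer_emission"] = {
            str(k): np.asarray(v).tolist() for k, v in echo["rotamer_emission"].items()
        }
    spec_path = os.path.join(outdir, "spec.json")
    with open(spec_path, "w") as fh:
        json.dump(echo, fh, indent=1, sort_keys=True)
    paths["spec"] = spec_path
    return paths
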