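"""Trajectory containers and I/O.

Reads standard topology/trajectory formats (PDB topology; DCD, XTC or
multi-model PDB trajectories) through MDAnalysis, selects backbone atoms,
superposes frames and exposes flat coordinate matrices to the analysis
stages.

Units are Angstrom internally (MDAnalysis converts on read). Frames are
0-indexed; residues are identified by their topology sequence number.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import MDAnalysis as mda

from ._geom import fit_frames

__all__ = [
    "Topology",
    "Replica",
    "TrajectoryEnsemble",
    "BackboneMatrix",
    "MissingAtomError",
    "FormatError",
    "load_ensemble",
    "write_ensemble",
    "extract_backbone",
    "superpose",
    "rmsf_per_residue",
    "write_bfactor_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C")


class FormatError(ValueError):
    """Topology/trajectory inconsistency (atom counts, empty files...)."""


class MissingAtomError(KeyError):
    """A residue lacks an atom required by the requested operation."""


@dataclass
class Topology:
    """Minimal residue/atom naming shared by all replicas of an ensemble."""

    residue_names: list[str]
    residue_ids: list[int]
    atom_names: list[str]
    atom_residue_index: np.ndarray  # per-atom 0-based residue index

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Flat index of a named atom in a residue, or MissingAtomError."""
        for i in np.flatnonzero(self.atom_residue_index == residue_index):
            if self.atom_names[i] == atom_name:
                return int(i)
        raise MissingAtomError(
            f"residue {self.residue_names[residue_index]}"
            f"{self.residue_ids[residue_index]} has no atom {atom_name!r}"
        )


@dataclass
class Replica:
    label: str
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_dt: float = 1.0
    replica_id: int = 0


@dataclass
class TrajectoryEnsemble:
    """A labeled set of replica trajectories sharing one topology."""

    topology: Topology
    replicas: list[Replica]

    def __post_init__(self) -> None:
        for rep in self.replicas:
            if rep.coords.ndim != 3 or rep.coords.shape[2] != 3:
                raise FormatError("replica coordinates must have shape (frames, atoms, 3)")
            if rep.coords.shape[1] != self.topology.n_atoms:
                raise FormatError(
                    f"replica {rep.label!r} has {rep.coords.shape[1]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )
            if rep.coords.shape[0] < 1:
                raise FormatError(f"replica {rep.label!r} has no frames")
        dts: dict[str, float] = {}
        for rep in self.replicas:
            if rep.label in dts and dts[rep.label] != rep.frame_dt:
                raise FormatError(f"replicas under label {rep.label!r} disagree on frame_dt")
            dts[rep.label] = rep.frame_dt

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for rep in self.replicas:
            if rep.label not in seen:
                seen.append(rep.label)
        return seen

    def subset(self, label: str) -> "TrajectoryEnsemble":
        reps = [r for r in self.replicas if r.label == label]
        if not reps:
            raise KeyError(f"no replicas labeled {label!r}")
        return TrajectoryEnsemble(self.topology, reps)


@dataclass
class BackboneMatrix:
    """Flat (n_frames, 3*n_backbone_atoms) coordinate matrix.

    Rows are ordered (replica, frame); columns are ordered by residue and
    then N, CA, C within each residue, xyz fastest.
    """

    frame_rows: np.ndarray
    atom_index: list[tuple[int, str]]  # (residue_index, atom name) per atom column triple
    labels: pd.DataFrame  # columns: label, replica, frame
    residue_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_rows.shape[1] % 3 != 0:
            raise ValueError("column count must be divisible by 3")
        if self.frame_rows.shape[1] != 3 * len(self.atom_index):
            raise ValueError("atom_index does not match column count")

    @property
    def n_frames(self) -> int:
        return self.frame_rows.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_index)

    def as_frames(self) -> np.ndarray:
        return self.frame_rows.reshape(self.n_frames, self.n_atoms, 3)

    def rows_for(self, label: str) -> np.ndarray:
        return np.flatnonzero((self.labels["label"] == label).to_numpy())


# ---------------------------------------------------------------------------
# Loading / writing


def _topology_from_universe(u: mda.Universe) -> Topology:
    atoms = u.atoms
    res_index = atoms.resindices.astype(int)
    return Topology(
        residue_names=[str(r) for r in u.residues.resnames],
        residue_ids=[int(i) for i in u.residues.resids],
        atom_names=[str(n) for n in atoms.names],
        atom_residue_index=res_index,
    )


def load_ensemble(
    topology_path: str | os.PathLike,
    trajectories: list[tuple[str, str]],
    frame_dt: float = 1.0,
) -> TrajectoryEnsemble:
    """Load replica trajectories sharing one topology.

    Parameters
    ----------
    topology_path:
        PDB file defining residue/atom naming.
    trajectories:
        List of ``(trajectory_path, ensemble_label)`` pairs. Formats are
        inferred from the file extension (DCD, XTC, or multi-model PDB).
    """
    if not trajectories:
        raise FormatError("no trajectories given")
    top_u = mda.Universe(str(topology_path))
    topology = _topology_from_universe(top_u)

    replicas: list[Replica] = []
    counts: dict[str, int] = {}
    for path, label in trajectories:
        if not os.path.exists(path):
            raise IOError(f"trajectory file not found: {path}")
        try:
            u = mda.Universe(str(topology_path), str(path))
        except (ValueError, IOError, EOFError) as exc:
            raise FormatError(f"cannot read trajectory {path}: {exc}") from exc
        if u.atoms.n_atoms != topology.n_atoms:
            raise FormatError(
                f"{path}: trajectory atom count {u.atoms.n_atoms} != "
                f"topology atom count {topology.n_atoms}"
            )
        n_frames = len(u.trajectory)
        if n_frames < 1:
            raise FormatError(f"{path}: trajectory contains no frames")
        coords = np.empty((n_frames, topology.n_atoms, 3), dtype=np.float64)
        for i, _ts in enumerate(u.trajectory):
            coords[i] = u.atoms.positions
        rid = counts.get(label, 0)
        counts[label] = rid + 1
        replicas.append(Replica(label=label, coords=coords, frame_dt=frame_dt, replica_id=rid))
    return TrajectoryEnsemble(topology=topology, replicas=replicas)


def _universe_from_topology(topology: Topology) -> mda.Universe:
    n_res = topology.n_residues
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=n_res,
        atom_resindex=topology.atom_residue_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.atom_names)
    u.add_TopologyAttr("resnames", topology.residue_names)
    u.add_TopologyAttr("resids", topology.residue_ids)
    u.add_TopologyAttr("elements", [n[:1] for n in topology.atom_names])
    u.add_TopologyAttr("tempfactors", np.zeros(topology.n_atoms))
    u.add_TopologyAttr("occupancies", np.ones(topology.n_atoms))
    return u


def write_topology_pdb(topology: Topology, coords: np.ndarray, path: str | os.PathLike) -> None:
    """Write a single-model PDB with the given coordinates (Angstrom)."""
    u = _universe_from_topology(topology)
    u.atoms.positions = np.asarray(coords, dtype=np.float32)
    with mda.Writer(str(path), n_atoms=topology.n_atoms, remarks="") as w:
        w.write(u.atoms)


def write_ensemble(
    ensemble: TrajectoryEnsemble,
    outdir: str | os.PathLike,
    trajectory_format: str = "dcd",
) -> dict[str, str]:
    """Write topology PDB + one trajectory file per replica.

    Returns a mapping of logical names to file paths. DCD is the default
    trajectory format (float32; round-trips Angstrom coordinates to ~1e-6);
    XTC is supported but stores fixed 0.001-nm precision.
    """
    os.makedirs(outdir, exist_ok=True)
    u = _universe_from_topology(ensemble.topology)
    paths: dict[str, str] = {}

    top_path = os.path.join(outdir, "topology.pdb")
    u.atoms.positions = ensemble.replicas[0].coords[0].astype(np.float32)
    with mda.Writer(top_path, n_atoms=ensemble.topology.n_atoms, remarks="") as w:
        w.write(u.atoms)
    paths["topology"] = top_path

    for rep in ensemble.replicas:
        name = f"traj_{rep.label}_{rep.replica_id}.{trajectory_format}"
        path = os.path.join(outdir, name)
        with mda.Writer(path, n_atoms=ensemble.topology.n_atoms) as w:
            for frame in rep.coords:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)
        paths[f"{rep.label}:{rep.replica_id}"] = path
    return paths


# ---------------------------------------------------------------------------
# Backbone extraction and superposition


def extract_backbone(
    ensemble: TrajectoryEnsemble,
    residue_selection: list[int] | None = None,
) -> BackboneMatrix:
    """Flatten N/CA/C coordinates of the selected residues.

    ``residue_selection`` lists 0-based residue indices; default all.
    Raises MissingAtomError naming the residue if a backbone atom is absent.
    """
    top = ensemble.topology
    if residue_selection is None:
        residue_selection = list(range(top.n_residues))
    cols: list[int] = []
    atom_index: list[tuple[int, str]] = []
    for res in residue_selection:
        for name in BACKBONE_ATOMS:
            cols.append(top.atom_index(res, name))
            atom_index.append((res, name))
    col_arr = np.asarray(cols)

    blocks = []
    rows = []
    for rep in ensemble.replicas:
        blocks.append(rep.coords[:, col_arr, :].reshape(rep.coords.shape[0], -1))
        for f in range(rep.coords.shape[0]):
            rows.append((rep.label, rep.replica_id, f))
    labels = pd.DataFrame(rows, columns=["label", "replica", "frame"])
    return BackboneMatrix(
        frame_rows=np.concatenate(blocks, axis=0),
        atom_index=atom_index,
        labels=labels,
        residue_ids=[top.residue_ids[r] for r in residue_selection],
    )


def superpose(matrix: BackboneMatrix, reference: str | int = "mean") -> BackboneMatrix:
    """Rigid-body least-squares fit of every frame to a common reference.

    ``reference`` is either a frame row index or ``"mean"``: one pass of
    fitting to the first frame, then refit to the coordinate-wise mean, so
    all ensembles share a single frame of reference.
    """
    frames = matrix.as_frames()
    if isinstance(reference, int):
        ref = frames[reference]
        fitted = fit_frames(frames, ref)
    else:
        first_pass = fit_frames(frames, frames[0])
        ref = first_pass.mean(axis=0)
        if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-8) < 2:
            raise np.linalg.LinAlgError("degenerate (collinear) reference coordinates")
        fitted = fit_frames(first_pass, ref)
    return BackboneMatrix(
        frame_rows=fitted.reshape(matrix.n_frames, -1),
        atom_index=matrix.atom_index,
        labels=matrix.labels.copy(),
        residue_ids=list(matrix.residue_ids),
    )


def rmsf_per_residue(
    matrix: BackboneMatrix, rows: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-residue backbone RMSF over the selected frame rows.

    For each residue, the mean squared fluctuation of its N/CA/C atoms
    about their mean positions is averaged over the three atoms before the
    square root. Also reports log10-scaled values for structure coloring.
    """
    if rows is None:
        rows = np.arange(matrix.n_frames)
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("empty frame subset")
    frames = matrix.as_frames()[rows]
    msf = ((frames - frames.mean(axis=0)) ** 2).sum(axis=-1).mean(axis=0)  # per atom

    res_of_atom = np.array([r for r, _ in matrix.atom_index])
    records = []
    for res in sorted(set(res_of_atom.tolist())):
        val = float(np.sqrt(msf[res_of_atom == res].mean()))
        records.append(
            {
                "residue_index": res,
                "rmsf": val,
                "log_rmsf": float(np.log10(val)) if val > 0 else -np.inf,
            }
        )
    return pd.DataFrame.from_records(records)


def write_bfactor_pdb(
    topology: Topology,
    coords: np.ndarray,
    per_residue_values: dict[int, float],
    path: str | os.PathLike,
) -> None:
    """Write a PDB whose B-factor column carries a per-residue scalar.

    ``per_residue_values`` maps 0-based residue index to the stamped value;
    residues not listed carry 0.
    """
    u = _universe_from_topology(topology)
    u.atoms.positions = np.asarray(coords, dtype=np.float32)
    temp = np.zeros(topology.n_atoms)
    for res, val in per_residue_values.items():
        temp[topology.atom_residue_index == res] = val
    u.atoms.tempfactors = temp
    with mda.Writer(str(path), n_atoms=topology.n_atoms, remarks="") as w:
        w.write(u.atoms)
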