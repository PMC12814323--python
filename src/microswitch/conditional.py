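"""Rotamer-conditioned conformational distributions.

Partitions an ensemble's PC-space frames by the rotamer state of a chosen
residue, histograms each partition on shared bin edges (so the per-state
histograms sum bin-wise to the unconditioned histogram), overlays
conditioned histograms across ensembles, and lists side-chain contacts of
representative frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microstates import ProjectedScores
from .rotamers import RotamerStateSeries
from .trajio import TrajectoryEnsemble

__all__ = [
    "ConditionalHistogramSet",
    "condition_histograms",
    "overlap_coefficient",
    "overlay",
    "contact_shell",
]


@dataclass
class StateHistogram:
    state: int
    fraction: float
    minor: bool
    hist2d: np.ndarray  # counts on shared edges
    hist_oblique: np.ndarray  # counts on shared 1-D edges


@dataclass
class ConditionalHistogramSet:
    residue_index: int
    edges_x: np.ndarray
    edges_y: np.ndarray
    edges_oblique: np.ndarray
    per_state: list[StateHistogram]
    total_hist2d: np.ndarray

    def __post_init__(self) -> None:
        fr = sum(s.fraction for s in self.per_state)
        if abs(fr - 1.0) > 1e-12:
            raise ValueError("per-state fractions must sum to 1")


def condition_histograms(
    scores: ProjectedScores,
    states: RotamerStateSeries,
    bins: int = 100,
    pc_pair: tuple[int, int] = (0, 1),
    oblique_angle: float = 60.0,
    minor_threshold: float = 0.05,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConditionalHistogramSet:
    """Histogram one ensemble's PC scores separately per rotamer state.

    All histograms are raw counts on shared edges; their bin-wise sum
    equals the unconditioned histogram exactly. Fractions report the share
    of frames per observed state; states under ``minor_threshold`` are
    flagged minor rather than dropped.
    """
    if scores.scores.shape[0] != len(states):
        raise ValueError(
            f"scores have {scores.scores.shape[0]} frames, "
            f"rotamer series has {len(states)}"
        )
    i, j = pc_pair
    x, y = scores.scores[:, i], scores.scores[:, j]
    if edges is None:
        ex = np.linspace(x.min(), x.max(), bins + 1)
        ey = np.linspace(y.min(), y.max(), bins + 1)
    else:
        ex, ey = edges
    theta = np.radians(oblique_angle)
    proj = x * np.cos(theta) + y * np.sin(theta)
    eo = np.linspace(proj.min(), proj.max(), (bins if isinstance(bins, int) else 100) + 1)

    total, _, _ = np.histogram2d(x, y, bins=(ex, ey))
    per_state: list[StateHistogram] = []
    n = len(states)
    for s in np.unique(states.states):
        mask = states.states == s
        h, _, _ = np.histogram2d(x[mask], y[mask], bins=(ex, ey))
        ho, _ = np.histogram(proj[mask], bins=eo)
        frac = mask.sum() / n
        per_state.append(
            StateHistogram(
                state=int(s),
                fraction=float(frac),
                minor=bool(frac < minor_threshold),
                hist2d=h,
                hist_oblique=ho,
            )
        )
    return ConditionalHistogramSet(
        residue_index=states.residue_index,
        edges_x=ex,
        edges_y=ey,
        edges_oblique=eo,
        per_state=per_state,
        total_hist2d=total,
    )


def overlap_coefficient(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    """Bin-wise min of the two probability-normalized grids, summed;
    1 for identical distributions, 0 for disjoint supports."""
    a, b = np.asarray(hist_a, float), np.asarray(hist_b, float)
    if a.shape != b.shape:
        raise ValueError("histogram shapes differ")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty histogram")
    return float(np.minimum(a / a.sum(), b / b.sum()).sum())


def overlay(
    layers: list[tuple[str, int, np.ndarray]],
    edges: tuple[np.ndarray, np.ndarray],
) -> pd.DataFrame:
    """Overlay table for plotting plus pairwise overlap coefficients.

    ``layers`` are (ensemble tag, rotamer state, histogram-on-shared-edges)
    triples; all histograms must be on the same grid.
    """
    shape = layers[0][2].shape
    for tag, state, h in layers:
        if h.shape != shape:
            raise ValueError(f"layer ({tag}, {state}) is not on the shared edges")
    records = []
    for a in range(len(layers)):
        for b in range(a + 1, len(layers)):
            records.append(
                {
                    "tag_a": layers[a][0],
                    "state_a": layers[a][1],
                    "tag_b": layers[b][0],
                    "state_b": layers[b][1],
                    "overlap": overlap_coefficient(layers[a][2], layers[b][2]),
                }
            )
    return pd.DataFrame.from_records(records)


def contact_shell(
    ensemble: TrajectoryEnsemble,
    replica: int,
    frame: int,
    residue_index: int,
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Residues with any heavy atom within ``cutoff`` (Angstrom, default 4)
    of the residue's side-chain heavy atoms in one frame.

    Hydrogens are ignored; the residue itself is excluded; the list is
    sorted by minimum distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = ensemble.topology
    if not 0 <= residue_index < top.n_residues:
        raise KeyError(f"unknown residue index {residue_index}")
    rep = ensemble.replicas[replica]
    coords = rep.coords[frame]

    heavy = np.array([not n.startswith("H") for n in top.atom_names])
    side = (
        (top.atom_residue_index == residue_index)
        & heavy
        & np.array([n not in ("N", "CA", "C", "O") for n in top.atom_names])
    )
    if not side.any():
        raise KeyError(
            f"residue {top.residue_names[residue_index]}{top.residue_ids[residue_index]} "
            "has no side-chain heavy atoms"
        )
    other = heavy & (top.atom_residue_index != residue_index)

    d = np.linalg.norm(
        coords[side][:, None, :] - coords[other][None, :, :], axis=-1
    ).min(axis=0)
    other_res = top.atom_residue_index[other]
    records = []
    for res in np.unique(other_res):
        dmin = float(d[other_res == res].min())
        if dmin <= cutoff:
            records.append(
                {
                    "residue_index": int(res),
                    "residue_name": top.residue_names[res],
                    "residue_id": top.residue_ids[res],
                    "min_distance": dmin,
                }
            )
    df = pd.DataFrame.from_records(
        records, columns=["residue_index", "residue_name", "residue_id", "min_distance"]
    )
    return df.sort_values("min_distance", kind="stable").reset_index(drop=True)
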