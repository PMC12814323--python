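"""Entropy-based cross-correlation (ECC) between categorical dynamics.

Two per-frame categorical series — the backbone microstate index and a
side chain's rotamer state index — are compared through their Shannon
entropies S_BB, S_SC and the joint entropy S_total:

    ECC = 2 (S_BB + S_SC - S_total) / (S_BB + S_SC)

If the series are statistically independent, S_total = S_BB + S_SC and
ECC = 0; if they determine one another, S_BB = S_SC = S_total and ECC = 1.
Natural logarithms are used; ECC is a ratio of entropies, so the log base
(and any Boltzmann prefactor) cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rotamers import EXCLUDED_RESIDUES, RotamerStateSeries

__all__ = [
    "ECCResult",
    "entropy",
    "joint_entropy",
    "ecc",
    "ecc_from_table",
    "ecc_scan",
    "shuffle_null",
    "results_table",
]


@dataclass
class ECCResult:
    residue_index: int | None
    residue_name: str | None
    s_bb: float
    s_sc: float
    s_total: float
    ecc: float
    n_frames: int
    degenerate: bool = False  # both series constant; ecc defined as 0


def _codes(series: np.ndarray) -> np.ndarray:
    return np.unique(np.asarray(series), return_inverse=True)[1]


def entropy(series: np.ndarray) -> float:
    """Shannon entropy (natural log) of the empirical state frequencies."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("empty series")
    counts = np.bincount(_codes(series))
    p = counts[counts > 0] / series.size
    return float(-np.sum(p * np.log(p)))


def joint_entropy(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Entropy of the paired-state series (a_t, b_t)."""
    a, b = np.asarray(series_a), np.asarray(series_b)
    if a.size != b.size:
        raise ValueError("series length mismatch")
    ca, cb = _codes(a), _codes(b)
    return entropy(ca * (cb.max() + 1) + cb)


def ecc(series_bb: np.ndarray, series_sc: np.ndarray) -> ECCResult:
    """ECC of two frame-aligned categorical series."""
    a, b = np.asarray(series_bb), np.asarray(series_sc)
    if a.size != b.size:
        raise ValueError("series length mismatch")
    s_bb = entropy(a)
    s_sc = entropy(b)
    if s_bb == 0.0 and s_sc == 0.0:
        return ECCResult(None, None, 0.0, 0.0, 0.0, 0.0, a.size, degenerate=True)
    s_total = joint_entropy(a, b)
    value = 2.0 * (s_bb + s_sc - s_total) / (s_bb + s_sc)
    # clip numerical fuzz at the exact endpoints
    value = min(1.0, max(0.0, value))
    return ECCResult(None, None, s_bb, s_sc, s_total, value, a.size)


def ecc_from_table(table: np.ndarray) -> ECCResult:
    """ECC computed directly from a joint count table (rows: backbone
    states, columns: side-chain states)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("empty table")
    rows, cols = np.nonzero(table)
    reps = table[rows, cols].astype(int)
    a = np.repeat(rows, reps)
    b = np.repeat(cols, reps)
    return ecc(a, b)


def ecc_scan(
    cluster_series: np.ndarray,
    rotamers: list[RotamerStateSeries],
    exclusions: frozenset[str] = EXCLUDED_RESIDUES,
) -> list[ECCResult]:
    """ECC of the backbone microstate series against each residue.

    The cluster series and every rotamer series must be frame-aligned
    (same ensemble, same frame order). Residue types in ``exclusions``
    (default Ala/Gly/Pro) are dropped. Results are sorted by residue
    index.
    """
    cluster_series = np.asarray(cluster_series)
    out: list[ECCResult] = []
    for rot in sorted(rotamers, key=lambda r: r.residue_index):
        if rot.residue_name in exclusions:
            continue
        if len(rot) != cluster_series.size:
            raise ValueError(
                f"residue {rot.residue_index}: rotamer series has {len(rot)} frames, "
                f"cluster series has {cluster_series.size}"
            )
        res = ecc(cluster_series, rot.states)
        res.residue_index = rot.residue_index
        res.residue_name = rot.residue_name
        out.append(res)
    return out


def shuffle_null(
    series_bb: np.ndarray,
    series_sc: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null ECC distribution from random permutations of the side-chain
    series. Off by default in scans; useful to judge the finite-sample
    floor of an observed ECC."""
    rng = np.random.default_rng(seed)
    sc = np.asarray(series_sc)
    return np.array(
        [ecc(series_bb, rng.permutation(sc)).ecc for _ in range(n_permutations)]
    )


def ecc_to_bfactor(
    results: list[ECCResult],
    topology,
    coords: np.ndarray,
    path,
) -> None:
    """Stamp per-residue ECC x 100 into the B-factor column of a PDB.

    All atoms of a residue carry its value (two-decimal PDB field);
    residues without a result carry 0.
    """
    from .trajio import write_bfactor_pdb

    values = {
        r.residue_index: 100.0 * r.ecc for r in results if r.residue_index is not None
    }
    write_bfactor_pdb(topology, coords, values, path)


def results_table(results: list[ECCResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "residue_index": r.residue_index,
                "residue_name": r.residue_name,
                "S_BB": r.s_bb,
                "S_SC": r.s_sc,
                "S_total": r.s_total,
                "ecc": r.ecc,
                "n_frames": r.n_frames,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
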