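"""Side-chain chi1/chi2 dihedrals and rotameric-state discretization.

A side chain's conformation is discretized by binning chi1 (and chi2 where
defined) into staggered or planar-flip wells; the state index is the
mixed-radix combination of the per-angle bin indices. The default scheme
gives the standard state counts: 3 for valine, 9 for leucine, 6 for
tryptophan. Alanine, glycine and proline carry no rotameric states and are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circmean

from ._geom import dihedral
from .trajio import MissingAtomError, TrajectoryEnsemble

__all__ = [
    "ChiSeries",
    "AngleBinning",
    "ResidueScheme",
    "RotamerScheme",
    "RotamerStateSeries",
    "NoChiError",
    "compute_chi",
    "build_default_scheme",
    "assign_states",
    "state_summary",
    "dwell_segments",
    "EXCLUDED_RESIDUES",
]

EXCLUDED_RESIDUES = frozenset({"ALA", "GLY", "PRO"})

# gamma atom closing the chi1 quadruple N-CA-CB-*, by residue type
_CHI1_GAMMA = {
    "VAL": "CG1",
    "ILE": "CG1",
    "SER": "OG",
    "THR": "OG1",
    "CYS": "SG",
}
# delta atom closing the chi2 quadruple CA-CB-CG-*, by residue type
_CHI2_DELTA = {
    "LEU": "CD1",
    "ILE": "CD1",
    "PHE": "CD1",
    "TYR": "CD1",
    "TRP": "CD1",
    "HIS": "ND1",
    "ASN": "OD1",
    "ASP": "OD1",
    "MET": "SD",
    "GLN": "CD",
    "GLU": "CD",
    "LYS": "CD",
    "ARG": "CD",
}
_CHI1_ONLY = frozenset({"VAL", "SER", "THR", "CYS"})
_CHI2_PLANAR = frozenset({"TRP", "PHE", "TYR", "HIS", "ASN", "ASP"})


class NoChiError(ValueError):
    """Requested chi angles for a residue type that has none."""


def wrap_angles(angles: np.ndarray | float) -> np.ndarray:
    """Wrap to the half-open interval (-180, 180]."""
    out = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(out == -180.0, 180.0, out)


@dataclass
class ChiSeries:
    """Per-frame chi1 (and optionally chi2) angles of one residue."""

    residue_index: int
    residue_name: str
    chi1: np.ndarray  # degrees, (-180, 180]
    chi2: np.ndarray | None = None
    labels: pd.DataFrame | None = None  # per-frame (label, replica, frame)

    def __post_init__(self) -> None:
        self.chi1 = wrap_angles(self.chi1)
        if self.chi2 is not None:
            self.chi2 = wrap_angles(self.chi2)
            if len(self.chi2) != len(self.chi1):
                raise ValueError("chi1/chi2 length mismatch")

    def __len__(self) -> int:
        return len(self.chi1)


@dataclass(frozen=True)
class AngleBinning:
    """Bin edges and labels for one chi angle.

    ``kind`` is "staggered" (3 wells split at -120/0/120: g-, g+, t) or
    "planar" (2 wells split at +-90: the ~0 deg face and the ~180 flip).
    """

    kind: str

    @property
    def n_bins(self) -> int:
        return 3 if self.kind == "staggered" else 2

    @property
    def labels(self) -> tuple[str, ...]:
        return ("g-", "g+", "t") if self.kind == "staggered" else ("0", "180")

    @property
    def centers(self) -> tuple[float, ...]:
        return (-60.0, 60.0, 180.0) if self.kind == "staggered" else (0.0, 180.0)

    def assign(self, angles: np.ndarray) -> np.ndarray:
        a = wrap_angles(angles)
        if self.kind == "staggered":
            idx = np.full(a.shape, 2, dtype=np.int64)  # trans by default
            idx[(a > -120.0) & (a <= 0.0)] = 0
            idx[(a > 0.0) & (a <= 120.0)] = 1
            return idx
        return np.where((a > -90.0) & (a <= 90.0), 0, 1).astype(np.int64)


@dataclass(frozen=True)
class ResidueScheme:
    residue_name: str
    angles: tuple[AngleBinning, ...]

    @property
    def n_states(self) -> int:
        n = 1
        for a in self.angles:
            n *= a.n_bins
        return n

    def state_label(self, state: int) -> str:
        parts = []
        for a in reversed(self.angles):
            parts.append(a.labels[state % a.n_bins])
            state //= a.n_bins
        return "/".join(reversed(parts))


@dataclass(frozen=True)
class RotamerScheme:
    """Discretization scheme mapping chi angles to rotameric states."""

    residue_schemes: dict[str, ResidueScheme] = field(default_factory=dict)

    def count(self, residue_name: str) -> int:
        if residue_name not in self.residue_schemes:
            raise NoChiError(f"{residue_name} has no rotameric states in this scheme")
        return self.residue_schemes[residue_name].n_states


def build_default_scheme() -> RotamerScheme:
    """The default chi1/chi2 binning.

    chi1 is always 3 staggered wells. chi2 is 3 staggered wells for sp3
    branches (Leu, Ile and the long chains truncated at chi2) and 2
    planar-flip wells for aromatics and planar amides/acids. Resulting
    counts: Val/Ser/Thr/Cys 3; Leu/Ile/Met/Gln/Glu/Lys/Arg 9;
    Trp/Phe/Tyr/His/Asn/Asp 6. Ala/Gly/Pro are excluded.
    """
    chi1 = AngleBinning("staggered")
    schemes: dict[str, ResidueScheme] = {}
    for name in _CHI1_ONLY:
        schemes[name] = ResidueScheme(name, (chi1,))
    for name in _CHI2_PLANAR:
        schemes[name] = ResidueScheme(name, (chi1, AngleBinning("planar")))
    for name in ("LEU", "ILE", "MET", "GLN", "GLU", "LYS", "ARG"):
        schemes[name] = ResidueScheme(name, (chi1, AngleBinning("staggered")))
    return RotamerScheme(residue_schemes=schemes)


@dataclass
class RotamerStateSeries:
    """Per-frame discrete rotamer index of one residue under a scheme."""

    residue_index: int
    residue_name: str
    states: np.ndarray  # per-frame state index
    scheme: ResidueScheme
    chi: ChiSeries | None = None

    def __post_init__(self) -> None:
        if np.any(self.states < 0) or np.any(self.states >= self.scheme.n_states):
            raise ValueError("state index outside the scheme's range")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def populations(self) -> np.ndarray:
        return np.bincount(self.states, minlength=self.scheme.n_states) / len(self.states)


# ---------------------------------------------------------------------------
# Operations


def _chi_quadruples(residue_name: str) -> list[tuple[str, str, str, str]]:
    if residue_name in EXCLUDED_RESIDUES:
        raise NoChiError(f"{residue_name} has no chi angles")
    quads = [("N", "CA", "CB", _CHI1_GAMMA.get(residue_name, "CG"))]
    if residue_name not in _CHI1_ONLY:
        gamma = _CHI1_GAMMA.get(residue_name, "CG")
        quads.append(("CA", "CB", gamma, _CHI2_DELTA[residue_name]))
    return quads


def compute_chi(
    ensemble: TrajectoryEnsemble, residue_indices: list[int]
) -> list[ChiSeries]:
    """Chi1/chi2 series for the requested residues over all replicas.

    Angles follow the standard sign convention and are wrapped to
    (-180, 180]. Frames of all replicas are concatenated in replica order,
    with per-frame (label, replica, frame) tags attached.
    """
    top = ensemble.topology
    out: list[ChiSeries] = []
    rows = []
    for rep in ensemble.replicas:
        for f in range(rep.coords.shape[0]):
            rows.append((rep.label, rep.replica_id, f))
    labels = pd.DataFrame(rows, columns=["label", "replica", "frame"])

    for res in residue_indices:
        rname = top.residue_names[res]
        quads = _chi_quadruples(rname)  # raises NoChiError for Ala/Gly/Pro
        angle_series = []
        for quad in quads:
            idx = [top.atom_index(res, a) for a in quad]  # raises MissingAtomError
            parts = [
                dihedral(
                    rep.coords[:, idx[0]],
                    rep.coords[:, idx[1]],
                    rep.coords[:, idx[2]],
                    rep.coords[:, idx[3]],
                )
                for rep in ensemble.replicas
            ]
            angle_series.append(np.concatenate(parts))
        out.append(
            ChiSeries(
                residue_index=res,
                residue_name=rname,
                chi1=angle_series[0],
                chi2=angle_series[1] if len(angle_series) > 1 else None,
                labels=labels,
            )
        )
    return out


def assign_states(chi: ChiSeries, scheme: RotamerScheme) -> RotamerStateSeries:
    """Discretize a chi series into rotamer state indices.

    The state is the mixed-radix combination of per-angle bin indices
    (chi1 most significant). Input angles may lie outside (-180, 180];
    they are wrapped, never rejected.
    """
    if chi.residue_name not in scheme.residue_schemes:
        raise NoChiError(f"{chi.residue_name} not covered by scheme")
    rscheme = scheme.residue_schemes[chi.residue_name]
    idx = rscheme.angles[0].assign(chi.chi1)
    if len(rscheme.angles) > 1:
        if chi.chi2 is None:
            raise MissingAtomError(f"residue {chi.residue_index}: chi2 required but absent")
        idx = idx * rscheme.angles[1].n_bins + rscheme.angles[1].assign(chi.chi2)
    return RotamerStateSeries(
        residue_index=chi.residue_index,
        residue_name=chi.residue_name,
        states=idx,
        scheme=rscheme,
        chi=chi,
    )


def _circular_mean(angles: np.ndarray) -> float:
    return float(wrap_angles(circmean(angles, high=180.0, low=-180.0)))


def state_summary(series: RotamerStateSeries, minor_threshold: float = 0.05) -> pd.DataFrame:
    """Per-state populations and circular-mean chi angles.

    States with population below ``minor_threshold`` (default 5%) are
    flagged as minor: such populations are reported but considered too
    sparse for further analysis. Populations sum to 1 before flagging.
    Only observed states appear, ordered by descending population
    ("state 1" = most populated).
    """
    if len(series) == 0:
        raise ValueError("empty state series")
    pops = series.populations
    observed = np.flatnonzero(pops > 0)
    order = observed[np.argsort(-pops[observed], kind="stable")]
    records = []
    for rank, s in enumerate(order, start=1):
        mask = series.states == s
        rec = {
            "rank": rank,
            "state": int(s),
            "label": series.scheme.state_label(int(s)),
            "population": float(pops[s]),
            "minor": bool(pops[s] < minor_threshold),
        }
        if series.chi is not None:
            rec["mean_chi1"] = _circular_mean(series.chi.chi1[mask])
            if series.chi.chi2 is not None:
                rec["mean_chi2"] = _circular_mean(series.chi.chi2[mask])
        records.append(rec)
    return pd.DataFrame.from_records(records)


def dwell_segments(
    series: RotamerStateSeries | np.ndarray,
    min_length: int,
    dominance: float = 0.9,
) -> list[tuple[int, int, int]]:
    """Single-state dwell windows of a categorical series.

    Returns non-overlapping maximal windows ``(start, end, state)`` (end
    exclusive) of length >= min_length in which one state's occupancy is
    >= ``dominance``, chosen greedily left to right (at each position the
    longest qualifying window is taken). A window shorter than the whole
    series may tolerate infrequent excursions to other states, mirroring
    "mostly fixed" chunk selection.
    """
    if not 0.5 < dominance <= 1.0:
        raise ValueError("dominance must lie in (0.5, 1]")
    states = series.states if isinstance(series, RotamerStateSeries) else np.asarray(series)
    n = len(states)
    if min_length < 1 or min_length > n:
        return []

    uniq = np.unique(states)
    # exact integer prefix counts per state; the occupancy test
    # count >= dominance * length is evaluated with one multiply, never
    # an accumulated float sum
    prefix = {int(s): np.concatenate([[0], np.cumsum(states == s)]) for s in uniq}
    # conservative prune: g[j] = count[j] - dominance*j is within float
    # error of the window criterion, so a suffix max of g rules out starts
    # with no valid window without risking a false reject
    g = {s: p - dominance * np.arange(n + 1) for s, p in prefix.items()}
    sufmax = {s: np.maximum.accumulate(v[::-1])[::-1] for s, v in g.items()}

    segments: list[tuple[int, int, int]] = []
    i = 0
    while i + min_length <= n:
        best_end = -1
        best_state = -1
        lo = i + min_length
        for s in uniq:
            s = int(s)
            if sufmax[s][lo] < g[s][i] - 1e-9:
                continue
            p = prefix[s]
            # largest j >= lo satisfying the exact criterion
            for j in range(n, lo - 1, -1):
                if p[j] - p[i] >= dominance * (j - i):
                    if j > best_end:
                        best_end, best_state = j, s
                    break
        if best_end >= 0:
            segments.append((i, best_end, best_state))
            i = best_end
        else:
            i += 1
    return segments
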