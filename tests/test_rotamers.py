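"""Chi dihedrals, rotamer binning, state summaries, dwell segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microswitch as ms
from microswitch._geom import dihedral, place_atom
from microswitch.rotamers import NoChiError, RotamerStateSeries, dwell_segments


class TestDihedralGeometry:
    def test_cis_is_zero_and_trans_is_180(self):
        a = np.array([1.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        c = np.array([0.0, 0.0, 0.0])
        d_cis = np.array([1.0, 0.0, 0.0])
        d_trans = np.array([-1.0, 0.0, 0.0])
        assert dihedral(a, b, c, d_cis) == pytest.approx(0.0, abs=1e-12)
        assert dihedral(a, b, c, d_trans) == pytest.approx(180.0, abs=1e-12)

    @pytest.mark.parametrize("target", [-150.0, -60.0, 0.0, 60.0, 97.3, 180.0])
    def test_constructed_torsion_recovered(self, target, rng):
        a, b, c = rng.normal(size=(3, 3))
        d = place_atom(a, b, c, 1.5, 109.5, target)
        assert dihedral(a, b, c, d) == pytest.approx(target, abs=1e-6)

    def test_agrees_with_mdanalysis(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        p = rng.normal(scale=2.0, size=(50, 4, 3))
        ours = dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        theirs = np.degrees(
            calc_dihedrals(*(np.ascontiguousarray(p[:, i]) for i in range(4)))
        )
        diff = np.abs(ours - theirs)
        # MDAnalysis computes in float32 internally
        assert np.minimum(diff, 360 - diff).max() < 1e-4


class TestComputeChi:
    def test_ala_gly_requests_rejected(self, small_ensemble):
        ens, _ = small_ensemble
        ala = [i for i, n in enumerate(ens.topology.residue_names) if n == "ALA"][0]
        with pytest.raises(NoChiError):
            ms.compute_chi(ens, [ala])

    def test_angles_wrapped(self, small_ensemble):
        ens, _ = small_ensemble
        chi = ms.compute_chi(ens, [1])[0]
        assert np.all(chi.chi1 > -180.0) and np.all(chi.chi1 <= 180.0)


class TestDefaultScheme:
    @pytest.mark.parametrize(
        "resname,count",
        [
            ("VAL", 3), ("LEU", 9), ("TRP", 6), ("PHE", 6), ("TYR", 6),
            ("HIS", 6), ("ASN", 6), ("ASP", 6), ("SER", 3), ("THR", 3),
            ("CYS", 3), ("ILE", 9), ("MET", 9), ("GLN", 9), ("GLU", 9),
            ("LYS", 9), ("ARG", 9),
        ],
    )
    def test_state_counts(self, scheme, resname, count):
        assert scheme.count(resname) == count
        rs = scheme.residue_schemes[resname]
        prod = 1
        for a in rs.angles:
            prod *= a.n_bins
        assert prod == count

    @pytest.mark.parametrize("resname", ["ALA", "GLY", "PRO"])
    def test_excluded_residues(self, scheme, resname):
        with pytest.raises(NoChiError):
            scheme.count(resname)


class TestAssignStates:
    def test_constant_gauche_minus_val(self, scheme):
        chi = ms.ChiSeries(0, "VAL", chi1=np.full(50, -60.0))
        s = ms.assign_states(chi, scheme)
        assert np.all(s.states == 0)
        assert np.allclose(s.populations, [1, 0, 0])

    def test_wrapping_invariance(self, scheme, rng):
        angles = rng.uniform(-180, 180, size=200)
        base = ms.assign_states(ms.ChiSeries(0, "VAL", chi1=angles.copy()), scheme)
        shifted = ms.assign_states(ms.ChiSeries(0, "VAL", chi1=angles + 360.0), scheme)
        assert np.array_equal(base.states, shifted.states)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 5))
    @settings(max_examples=20, deadline=None)
    def test_wrapping_invariance_any_multiple(self, seed, k):
        scheme = ms.build_default_scheme()
        angles = np.random.default_rng(seed).uniform(-180, 180, size=50)
        a = ms.assign_states(ms.ChiSeries(0, "LEU", chi1=angles, chi2=-angles), scheme)
        b = ms.assign_states(
            ms.ChiSeries(0, "LEU", chi1=angles + 360.0 * k, chi2=-angles - 360.0 * k),
            scheme,
        )
        assert np.array_equal(a.states, b.states)

    def test_populations_sum_to_one(self, scheme, rng):
        chi = ms.ChiSeries(0, "TRP", chi1=rng.uniform(-180, 180, 997),
                           chi2=rng.uniform(-180, 180, 997))
        s = ms.assign_states(chi, scheme)
        assert abs(s.populations.sum() - 1.0) < 1e-12

    def test_kappa_one_fixture_recovered(self, scheme):
        spec = ms.SyntheticSpec(
            n_ensembles=1, replicas_per_ensemble=1, n_frames=5000,
            n_residues=4, residue_names=["ALA", "TRP", "GLY", "ALA"],
            n_microstates=4, coupled_residues=[(1, 1.0)], seed=9,
        )
        fx = ms.dihedral_only_fixture(spec)
        chi = ms.ChiSeries(1, "TRP", chi1=fx.chi1[1], chi2=fx.chi2[1])
        s = ms.assign_states(chi, scheme)
        assert np.mean(s.states == fx.rotamer_states[1]) >= 0.999


class TestStateSummary:
    def test_single_state(self, scheme):
        chi = ms.ChiSeries(0, "VAL", chi1=np.full(10, 60.0))
        table = ms.state_summary(ms.assign_states(chi, scheme))
        assert len(table) == 1
        assert table.loc[0, "population"] == 1.0

    def test_minor_state_flagged_at_default_threshold(self, scheme):
        chi1 = np.concatenate([np.full(97, -60.0), np.full(3, 60.0)])
        table = ms.state_summary(ms.assign_states(ms.ChiSeries(0, "VAL", chi1=chi1), scheme))
        assert not table.loc[0, "minor"] and table.loc[1, "minor"]
        assert table["population"].sum() == pytest.approx(1.0)

    def test_circular_mean_across_branch_cut(self, scheme):
        chi1 = np.array([-170.0, 170.0] * 10)
        table = ms.state_summary(ms.assign_states(ms.ChiSeries(0, "VAL", chi1=chi1), scheme))
        assert table.loc[0, "mean_chi1"] == pytest.approx(180.0, abs=1e-9)

    def test_ranked_by_descending_population(self, scheme, rng):
        chi1 = np.concatenate([np.full(10, -60.0), np.full(70, 60.0), np.full(20, 180.0)])
        table = ms.state_summary(ms.assign_states(ms.ChiSeries(0, "VAL", chi1=chi1), scheme))
        assert table["population"].is_monotonic_decreasing
        assert table.loc[0, "rank"] == 1


def dwell_oracle(states, min_length, dominance):
    """Exhaustive reference: at each start take the longest window whose
    dominant state reaches the occupancy bound; emit greedily left to
    right."""
    n = len(states)
    segs = []
    i = 0
    while i + min_length <= n:
        best = None
        for j in range(n, i + min_length - 1, -1):
            win = states[i:j]
            counts = np.bincount(win)
            if counts.max() >= dominance * (j - i):
                best = (i, j, int(np.argmax(counts)))
                break
        if best:
            segs.append(best)
            i = best[1]
        else:
            i += 1
    return segs


class TestDwellSegments:
    def test_constant_series_single_segment(self):
        s = np.zeros(100, dtype=int)
        assert dwell_segments(s, 100, 0.9) == [(0, 100, 0)]

    def test_alternating_series_has_no_segments(self):
        s = np.tile([0, 1], 50)
        assert dwell_segments(s, 10, 0.9) == []

    def test_min_length_beyond_series_is_empty(self):
        assert dwell_segments(np.zeros(10, dtype=int), 11, 0.9) == []

    def test_bad_dominance_rejected(self):
        with pytest.raises(ValueError):
            dwell_segments(np.zeros(10, dtype=int), 2, 0.4)

    def test_planted_dwells_recovered(self, rng):
        # three long single-state stretches separated by scrambled gaps
        parts = [
            rng.integers(0, 3, 60),
            np.full(300, 1), rng.integers(0, 3, 80),
            np.full(250, 0), rng.integers(0, 3, 70),
            np.full(240, 2),
        ]
        s = np.concatenate(parts)
        segs = dwell_segments(s, 200, 0.9)
        assert segs == dwell_oracle(s, 200, 0.9)
        assert [seg[2] for seg in segs] == [1, 0, 2]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_bruteforce_on_sticky_series(self, seed):
        rng = np.random.default_rng(seed)
        # sticky 3-state chain, 400 frames
        s = np.empty(400, dtype=int)
        s[0] = rng.integers(3)
        for t in range(1, 400):
            s[t] = s[t - 1] if rng.random() < 0.95 else rng.integers(3)
        for min_len, dom in [(50, 0.9), (100, 0.8), (30, 1.0)]:
            assert dwell_segments(s, min_len, dom) == dwell_oracle(s, min_len, dom)

    def test_accepts_state_series_objects(self, scheme):
        chi = ms.ChiSeries(0, "VAL", chi1=np.full(30, -60.0))
        series = ms.assign_states(chi, scheme)
        assert dwell_segments(series, 30, 0.9) == [(0, 30, 0)]
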