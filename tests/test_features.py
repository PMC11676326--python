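"""Per-fragment features: confidence summaries, orientation, knobs-into-holes."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coilscan.features import (
    detect_kih,
    detect_orientation,
    mean_pae_per_residue,
    mean_plddt_per_residue,
    pair_orientation,
)
from coilscan.model_io import FragmentModel
from coilscan.synthetic import (
    CrickParams,
    add_coordinate_noise,
    crick_backbone,
    translate_chains_apart,
)


def _model(ca_per_chain, pae=None, plddt=None, sc=None):
    n = len(ca_per_chain)
    length = len(ca_per_chain[0])
    return FragmentModel(
        chain_ids=[chr(65 + i) for i in range(n)],
        residue_numbers=[np.arange(1, length + 1)] * n,
        ca=[np.asarray(c, dtype=float) for c in ca_per_chain],
        sc_centers=[np.asarray(c, dtype=float) for c in (sc or ca_per_chain)],
        plddt=[np.asarray(p, dtype=float) for p in plddt]
        if plddt is not None
        else [np.full(length, 50.0)] * n,
        pae=None if pae is None else np.asarray(pae, dtype=float),
    )


def _rigid_transform(model, rng):
    rot = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31))))
    shift = rng.uniform(-50, 50, 3)
    out = FragmentModel(
        chain_ids=list(model.chain_ids),
        residue_numbers=[r.copy() for r in model.residue_numbers],
        ca=[rot.apply(c) + shift for c in model.ca],
        sc_centers=[rot.apply(s) + shift for s in model.sc_centers],
        plddt=[p.copy() for p in model.plddt],
        pae=model.pae,
    )
    return out


class TestConfidenceSummaries:
    def test_mean_plddt_averages_chains(self):
        m = _model(
            [np.zeros((3, 3)), np.zeros((3, 3))],
            plddt=[[80, 90, 100], [60, 70, 80]],
        )
        np.testing.assert_allclose(mean_plddt_per_residue(m), [70, 80, 90])

    def test_monomer_plddt_is_identity(self):
        m = _model([np.zeros((4, 3))], plddt=[[10, 20, 30, 40]])
        np.testing.assert_allclose(mean_plddt_per_residue(m), [10, 20, 30, 40])

    def test_constant_pae(self):
        m = _model([np.zeros((3, 3)), np.zeros((3, 3))], pae=np.full((6, 6), 5.0))
        np.testing.assert_allclose(mean_pae_per_residue(m), [5.0, 5.0, 5.0])

    def test_zero_pae_monomer(self):
        m = _model([np.zeros((4, 3))], pae=np.zeros((4, 4)))
        np.testing.assert_allclose(mean_pae_per_residue(m), np.zeros(4))

    def test_asymmetric_pae_row_and_column_mean(self):
        # rows and columns both count, diagonal included: (0+4+2+0)/4 = 1.5
        m = _model([np.zeros((2, 3))], pae=[[0, 4], [2, 0]])
        np.testing.assert_allclose(mean_pae_per_residue(m), [1.5, 1.5])

    def test_absent_pae_reports_missing(self):
        m = _model([np.zeros((3, 3))])
        assert mean_pae_per_residue(m) is None

    def test_dimer_pae_oracle(self, rng):
        """Brute-force row/column enumeration over both chain copies."""
        length = 5
        pae = rng.uniform(0, 30, (10, 10))
        m = _model([np.zeros((length, 3)), np.zeros((length, 3))], pae=pae)
        got = mean_pae_per_residue(m)
        for i in range(length):
            idx = [i, length + i]
            vals = [pae[r, j] for r in idx for j in range(10)] + [
                pae[j, c] for c in idx for j in range(10)
            ]
            assert got[i] == pytest.approx(sum(vals) / len(vals))


class TestOrientation:
    def test_parallel_dimer(self, parallel_dimer):
        assert detect_orientation(parallel_dimer) == 1.0

    def test_antiparallel_dimer(self, antiparallel_dimer):
        assert detect_orientation(antiparallel_dimer) == 0.0

    def test_reversing_one_chain_flips_the_call(self, parallel_dimer):
        m = parallel_dimer
        flipped = _model([m.ca[0], m.ca[1][::-1]])
        assert detect_orientation(flipped) == 0.0
        d_fwd, d_rev, _ = pair_orientation(m.ca[0], m.ca[1])
        f2, r2, _ = pair_orientation(m.ca[0], m.ca[1][::-1])
        assert d_fwd == pytest.approx(r2) and d_rev == pytest.approx(f2)

    def test_up_down_tetramer_majority(self):
        m = crick_backbone(CrickParams.for_bundle(4, 28, parallel=False))
        # 4 of 6 unordered pairs are antiparallel
        calls = [
            pair_orientation(m.ca[a], m.ca[b])[2]
            for a, b in combinations(range(4), 2)
        ]
        assert sum(calls) == 2
        assert detect_orientation(m) == 0.0

    def test_monomer_orientation_undefined(self):
        m = crick_backbone(CrickParams(n_chains=1, chain_length=21))
        assert detect_orientation(m) is None

    def test_tie_gives_half(self):
        # three up chains and one down chain: the 3 up-up pairs are
        # parallel, the 3 up-down pairs antiparallel -> exact 3:3 tie
        z = np.linspace(0, 30, 11)
        up = np.column_stack([np.zeros(11), np.zeros(11), z])
        chains = [up, up + [6.0, 0, 0], up + [0, 6.0, 0], up[::-1] + [3.0, 3.0, 0]]
        m = _model(chains)
        calls = [
            pair_orientation(m.ca[a], m.ca[b])[2]
            for a, b in combinations(range(4), 2)
        ]
        assert sum(calls) == 3
        assert detect_orientation(m) == 0.5

    def test_pairwise_call_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 5))
            parallel = bool(rng.integers(0, 2))
            m = crick_backbone(
                CrickParams.for_bundle(n, int(rng.integers(21, 40)), parallel=parallel)
            )
            m = add_coordinate_noise(m, 0.2, rng)
            for a, b in combinations(range(n), 2):
                d_fwd, d_rev, is_par = pair_orientation(m.ca[a], m.ca[b])
                length = m.n_residues
                bf_fwd = sum(
                    math.dist(m.ca[a][i], m.ca[b][i]) for i in range(length)
                ) / length
                bf_rev = sum(
                    math.dist(m.ca[a][i], m.ca[b][length - 1 - i]) for i in range(length)
                ) / length
                assert d_fwd == pytest.approx(bf_fwd)
                assert d_rev == pytest.approx(bf_rev)
                assert is_par == (bf_rev >= bf_fwd)


def kih_oracle(model, cutoff=7.0):
    """Brute-force all-pairs knob detection with plain Python loops."""
    knobs = set()
    for x in range(model.n_chains):
        for r in range(model.n_residues):
            for y in range(model.n_chains):
                if y == x:
                    continue
                close = [
                    s for s in range(model.n_residues)
                    if math.dist(model.sc_centers[x][r], model.sc_centers[y][s]) <= cutoff
                ]
                if len(close) >= 4:
                    knobs.add((x, r))
    return knobs


class TestKih:
    def test_matches_brute_force_oracle(self, parallel_dimer, rng):
        noisy = add_coordinate_noise(parallel_dimer, 0.15, rng)
        ann = detect_kih(noisy)
        got = {(c, r) for c in range(2) for r in np.flatnonzero(ann.is_knob[c])}
        assert got == kih_oracle(noisy)

    def test_separated_chains_have_no_knobs(self, parallel_dimer):
        far = translate_chains_apart(parallel_dimer, spacing=100.0)
        ann = detect_kih(far)
        assert not ann.is_knob.any() and not ann.in_hole.any()

    def test_monomer_all_false(self):
        m = crick_backbone(CrickParams(n_chains=1, chain_length=21))
        ann = detect_kih(m)
        assert not ann.participates.any()

    def test_hole_residues_on_partner_chain_within_cutoff(self, parallel_dimer):
        ann = detect_kih(parallel_dimer)
        assert ann.is_knob.any()
        for (chain, res), hole in ann.holes.items():
            partner = ann.partner_chain[chain, res]
            assert partner != chain and len(hole) == 4
            for h in hole:
                d = np.linalg.norm(
                    parallel_dimer.sc_centers[chain][res]
                    - parallel_dimer.sc_centers[partner][h]
                )
                assert d <= 7.0

    def test_shrinking_cutoff_never_creates_knobs(self, parallel_dimer, rng):
        noisy = add_coordinate_noise(parallel_dimer, 0.2, rng)
        previous = None
        for cutoff in (8.0, 7.0, 6.0, 5.0):
            knobs = {
                (c, r)
                for c in range(2)
                for r in np.flatnonzero(detect_kih(noisy, cutoff).is_knob[c])
            }
            if previous is not None:
                assert knobs <= previous
            previous = knobs


class TestInvariances:
    @pytest.mark.parametrize("n_chains, parallel", [(2, True), (3, False), (4, True)])
    def test_rigid_body_invariance(self, n_chains, parallel, rng):
        m = crick_backbone(CrickParams.for_bundle(n_chains, 28, parallel=parallel))
        m.pae = rng.uniform(0, 20, (n_chains * 28, n_chains * 28))
        moved = _rigid_transform(m, rng)
        assert detect_orientation(moved) == detect_orientation(m)
        np.testing.assert_allclose(
            mean_plddt_per_residue(moved), mean_plddt_per_residue(m), atol=1e-6
        )
        np.testing.assert_allclose(
            mean_pae_per_residue(moved), mean_pae_per_residue(m), atol=1e-6
        )
        np.testing.assert_array_equal(
            detect_kih(moved).per_position(), detect_kih(m).per_position()
        )

    def test_chain_relabeling_invariance(self, rng):
        m = crick_backbone(CrickParams.for_bundle(4, 28, parallel=False))
        perm = rng.permutation(4)
        shuffled = FragmentModel(
            chain_ids=[m.chain_ids[i] for i in perm],
            residue_numbers=[m.residue_numbers[i] for i in perm],
            ca=[m.ca[i] for i in perm],
            sc_centers=[m.sc_centers[i] for i in perm],
            plddt=[m.plddt[i] for i in perm],
        )
        assert detect_orientation(shuffled) == detect_orientation(m)
        np.testing.assert_allclose(
            mean_plddt_per_residue(shuffled), mean_plddt_per_residue(m)
        )
        np.testing.assert_array_equal(
            detect_kih(shuffled).per_position(), detect_kih(m).per_position()
        )
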