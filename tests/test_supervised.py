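"""Supervised pipeline: switching function, CV tables, spectral clustering,
motif naming, and block-averaged defect counting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fiberex.engine import Trajectory, build_stack
from fiberex.fixtures import render_cv_rows
from fiberex.monomer import variant_monomer
from fiberex.supervised import (
    COORD_PARAMS,
    CVTable,
    CV_COLUMNS,
    SwitchingParams,
    assign_motifs,
    compute_cv_table,
    count_defects,
    spectral_cluster,
    switching,
)
from fiberex.surrogate import BULK, DEFECT, TIP, SOLVENT


class TestSwitching:
    def test_limits(self):
        p = SwitchingParams(r0=1.0, dmax=3.0)
        assert switching(0.0, p) == 1.0
        assert switching(3.0, p) == 0.0
        assert switching(10.0, p) == 0.0

    def test_value_near_half_at_r0(self):
        # the rational form tends to 1/2 at r = r0; stretching moves it
        # only slightly when dmax >> r0
        p = SwitchingParams(r0=1.0, dmax=10.0)
        assert switching(1.0, p) == pytest.approx(0.5, abs=0.01)

    def test_monotone_nonincreasing(self):
        p = COORD_PARAMS
        r = np.linspace(0.0, 5.0, 400)
        assert np.all(np.diff(switching(r, p)) <= 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SwitchingParams(r0=2.0, dmax=1.0)
        with pytest.raises(ValueError):
            SwitchingParams(r0=1.0, dmax=2.0, n=12, m=6)


class TestComputeCVTable:
    @pytest.fixture(scope="class")
    def stack_table(self):
        sys_ = build_stack(10, spec=variant_monomer(1))
        traj = Trajectory(
            frames=sys_.positions[None, :, :], times=np.array([0.0]), system=sys_
        )
        return compute_cv_table(traj)

    def test_interior_rows_bulk_signature(self, stack_table):
        df = stack_table.data.xs(0, level="frame")
        interior = df.iloc[1:-1]
        assert np.allclose(interior["coordination"], 2.0, atol=0.35)
        assert np.allclose(interior["min_core_distance"], 1.0, atol=0.05)

    def test_tip_rows_coordination_one(self, stack_table):
        df = stack_table.data.xs(0, level="frame")
        for i in (0, 9):
            assert df["coordination"].iloc[i] == pytest.approx(1.0, abs=0.35)

    def test_end_flags_mark_the_two_tips(self, stack_table):
        flags = stack_table.end_flags.xs(0, level="frame")
        assert flags.sum() == 2 and flags.iloc[0] and flags.iloc[9]

    def test_displaced_monomer_min_distance_beyond_2c(self):
        sys_ = build_stack(10, spec=variant_monomer(1))
        pos = sys_.positions.copy()
        mask = sys_.monomer_id == 9
        pos[mask] += np.array([0.0, 0.0, 3.0 * 1.12])
        traj = Trajectory(frames=pos[None], times=np.array([0.0]), system=sys_)
        table = compute_cv_table(traj, c=1.12)
        assert table.data.xs(0, level="frame")["min_core_distance"].iloc[9] > 2.0


class TestSpectralCluster:
    def test_three_blobs_perfect_recovery(self, bundle):
        X, y = bundle["three_blobs"]
        idx = pd.MultiIndex.from_product(
            [range(1), range(X.shape[0])], names=["frame", "monomer"]
        )
        table = CVTable(data=pd.DataFrame(X, columns=CV_COLUMNS, index=idx), c=1.0)
        ids = spectral_cluster(table, k=3, seed=0)
        assert adjusted_rand_score(y, ids) == 1.0

    def test_k_one_single_cluster(self, bundle):
        X, _ = bundle["three_blobs"]
        idx = pd.MultiIndex.from_product(
            [range(1), range(X.shape[0])], names=["frame", "monomer"]
        )
        table = CVTable(data=pd.DataFrame(X, columns=CV_COLUMNS, index=idx), c=1.0)
        assert set(spectral_cluster(table, k=1)) == {0}

    def test_duplication_invariance(self, bundle):
        X, _ = bundle["three_blobs"]
        idx1 = pd.MultiIndex.from_product(
            [range(1), range(X.shape[0])], names=["frame", "monomer"]
        )
        t1 = CVTable(data=pd.DataFrame(X, columns=CV_COLUMNS, index=idx1), c=1.0)
        X2 = np.vstack([X, X])
        idx2 = pd.MultiIndex.from_product(
            [range(2), range(X.shape[0])], names=["frame", "monomer"]
        )
        t2 = CVTable(data=pd.DataFrame(X2, columns=CV_COLUMNS, index=idx2), c=1.0)
        a = spectral_cluster(t1, k=3, seed=0)
        b = spectral_cluster(t2, k=3, seed=0)[: X.shape[0]]
        assert adjusted_rand_score(a, b) == 1.0

    def test_degenerate_table_rejected(self):
        idx = pd.MultiIndex.from_product(
            [range(1), range(10)], names=["frame", "monomer"]
        )
        X = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        table = CVTable(data=pd.DataFrame(X, columns=CV_COLUMNS, index=idx), c=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            spectral_cluster(table, k=3)


def _states_block(rows):
    return np.array(rows, dtype=np.int8)


class TestAssignMotifs:
    def test_fiber1_like_partition(self):
        # tips + bulk + spontaneously exchanged monomers, no defects
        states = np.full((60, 12), BULK, dtype=np.int8)
        states[:, 0] = states[:, -1] = TIP
        states[30:, 5] = SOLVENT
        table = render_cv_rows(states, seed=0)
        labels = assign_motifs(spectral_cluster(table, k=3, seed=0), table)
        found = set(labels.labels.unique())
        assert found == {"BULK", "TIP", "EXCHANGED"}

    def test_fiber3_like_partition_no_exchanged(self):
        states = np.full((60, 12), BULK, dtype=np.int8)
        states[:, 0] = states[:, -1] = TIP
        states[:, 3] = DEFECT
        states[20:, 7] = DEFECT
        table = render_cv_rows(states, seed=1)
        labels = assign_motifs(spectral_cluster(table, k=3, seed=0), table)
        found = set(labels.labels.unique())
        assert "DEFECT" in found and "EXCHANGED" not in found

    def test_all_bulk_rows_zero_defects(self):
        states = np.full((20, 10), BULK, dtype=np.int8)
        table = render_cv_rows(states, seed=2)
        labels = assign_motifs(np.zeros(200, dtype=int), table)
        assert (labels.labels == "BULK").all()
        assert labels.defect_counts().sum() == 0

    def test_end_to_end_state_recovery(self, fiber3_states):
        # surrogate states -> canonical CV rows -> clustering + naming
        # recovers the per-row ground truth almost perfectly
        table = render_cv_rows(fiber3_states, seed=3)
        labels = assign_motifs(spectral_cluster(table, k=3, seed=0), table)
        truth = np.array(["BULK", "DEFECT", "TIP", "EXCHANGED"])[
            fiber3_states.ravel()
        ]
        agreement = (labels.labels.to_numpy() == truth).mean()
        assert agreement >= 0.99


class TestCountDefects:
    def _labels_from_counts(self, counts, n_mono=14):
        frames = len(counts)
        states = np.full((frames, n_mono), BULK, dtype=np.int8)
        for f, k in enumerate(counts):
            states[f, 1 : 1 + k] = DEFECT
        idx = pd.MultiIndex.from_product(
            [range(frames), range(n_mono)], names=["frame", "monomer"]
        )
        names = np.array(["BULK", "DEFECT", "TIP", "EXCHANGED"])[states.ravel()]
        from fiberex.supervised import MotifLabels

        return MotifLabels(
            labels=pd.Series(names, index=idx),
            cluster_ids=np.zeros(states.size, dtype=int),
            centroids=pd.DataFrame(),
            cluster_motif={},
        )

    def test_constant_counts(self):
        labels = self._labels_from_counts([12] * 40)
        mean, se = count_defects(labels, block_size=10.0, t_stride=1.0)
        assert mean == 12.0 and se == 0.0

    def test_alternating_counts_average(self):
        labels = self._labels_from_counts([0, 2] * 30)
        mean, se = count_defects(labels, block_size=20.0, t_stride=1.0)
        assert mean == pytest.approx(1.0)

    def test_frame_reordering_within_blocks_invariant(self):
        rng = np.random.default_rng(5)
        counts = list(rng.integers(0, 5, 40))
        labels = self._labels_from_counts(counts)
        m1, _ = count_defects(labels, block_size=20.0, t_stride=1.0)
        # permute frames inside each block of 20
        perm = np.concatenate([rng.permutation(20), 20 + rng.permutation(20)])
        labels2 = self._labels_from_counts([counts[i] for i in perm])
        m2, _ = count_defects(labels2, block_size=20.0, t_stride=1.0)
        assert m1 == pytest.approx(m2)

    def test_insufficient_blocks_rejected(self):
        labels = self._labels_from_counts([1] * 5)
        with pytest.raises(ValueError, match="blocks"):
            count_defects(labels, block_size=10.0, t_stride=1.0)

    def test_surrogate_defect_count_matches_closed_form(self, bundle):
        st = bundle["surrogate_triplet"][2]  # k_bd 0.3, k_db 14
        states = st.states
        table = render_cv_rows(states[::5], seed=6)
        labels = assign_motifs(spectral_cluster(table, k=3, seed=0), table)
        mean, se = count_defects(labels, block_size=2.0, t_stride=st.t_stride * 5)
        expected = 38 * 0.3 / 14.3
        assert abs(mean - expected) < max(3 * se, 0.15)
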