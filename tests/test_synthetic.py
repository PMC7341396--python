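"""Tests for the synthetic cohort generator."""

import numpy as np
import pytest

from adgraph import (CohortConfig, RSNPartition, build_stage_covariance,
                     correlation_matrix, default_partition, generate_cohort,
                     read_cohort, read_partition, write_cohort, write_partition)
from adgraph.synthetic import DEFAULT_MMSE_PARAMS, STAGES


def two_block_config(**kw):
    part = RSNPartition(networks=("A", "B"),
                        assignment={0: "A", 1: "A", 2: "B", 3: "B"})
    defaults = dict(
        n_rois=4, n_timepoints=40, partition=part,
        group_sizes={"NC": 2, "EMCI": 2, "LMCI": 2, "AD": 2},
        within_r={"A": (0.3, 0.45, 0.35, 0.2), "B": (0.45, 0.38, 0.3, 0.22)},
        network_patterns={"A": "inversion", "B": "decline"},
        between_r=0.1, min_timepoints=10,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestStageCovariance:
    def test_zero_correlations_give_identity(self):
        cfg = two_block_config(within_r={"A": (0.0,) * 4, "B": (0.0,) * 4},
                               network_patterns={}, between_r=0.0)
        np.testing.assert_array_equal(build_stage_covariance(cfg, "NC"), np.eye(4))

    def test_two_block_construction(self):
        cfg = two_block_config(within_r={"A": (0.5,) * 4, "B": (0.5,) * 4},
                               network_patterns={}, between_r=0.1)
        cov = build_stage_covariance(cfg, "LMCI")
        expected = np.array([
            [1.0, 0.5, 0.1, 0.1],
            [0.5, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.5],
            [0.1, 0.1, 0.5, 1.0],
        ])
        np.testing.assert_allclose(cov, expected)

    def test_u_shape_readback_across_stages(self):
        """The four stage covariances reproduce the configured trajectory."""
        cfg = CohortConfig(seed=0)
        part = cfg.resolved_partition()
        idx = part.indices("DMN")
        readback = []
        for stage in STAGES:
            cov = build_stage_covariance(cfg, stage)
            block = cov[np.ix_(idx, idx)]
            off = block[~np.eye(len(idx), dtype=bool)]
            assert np.unique(off).size == 1
            readback.append(off[0])
        assert tuple(readback) == cfg.within_r["DMN"]

    def test_covariance_positive_definite(self):
        for stage in STAGES:
            cov = build_stage_covariance(CohortConfig(), stage)
            assert np.linalg.eigvalsh(cov)[0] > 0

    def test_invalid_inversion_trajectory_rejected(self):
        cfg = two_block_config(within_r={"A": (0.5, 0.4, 0.3, 0.2), "B": (0.45, 0.38, 0.3, 0.22)})
        with pytest.raises(ValueError, match="peak at EMCI"):
            cfg.validate()

    def test_negative_mmse_sd_rejected(self):
        cfg = two_block_config(mmse_params={**DEFAULT_MMSE_PARAMS, "AD": (22.7, -1.0)})
        with pytest.raises(ValueError, match="sd"):
            cfg.validate()


class TestGenerateCohort:
    def test_default_cohort_size_matches_group_table(self):
        cohort = generate_cohort(CohortConfig(seed=3, n_timepoints=30, n_rois=10,
                                              partition=default_partition(10)))
        assert len(cohort) == 130
        by_stage = {s: sum(1 for c in cohort if c.stage == s) for s in STAGES}
        assert by_stage == {"NC": 35, "EMCI": 37, "LMCI": 33, "AD": 25}

    def test_all_group_sizes_zero_gives_empty_cohort(self):
        cfg = two_block_config(group_sizes={s: 0 for s in STAGES})
        assert generate_cohort(cfg) == []

    def test_mmse_monte_carlo_mean(self):
        """Sample mean of many AD MMSE draws matches the configured 22.72."""
        cfg = two_block_config(group_sizes={"NC": 0, "EMCI": 0, "LMCI": 0, "AD": 10_000},
                               n_timepoints=10, min_timepoints=5, seed=123)
        cohort = generate_cohort(cfg)
        scores = np.array([c.mmse for c in cohort])
        assert scores.mean() == pytest.approx(22.72, abs=0.1)
        assert scores.min() >= 0 and scores.max() <= 30

    def test_seed_reproducibility(self):
        a = generate_cohort(two_block_config(seed=9))
        b = generate_cohort(two_block_config(seed=9))
        c = generate_cohort(two_block_config(seed=10))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)
            assert x.mmse == y.mmse
        assert any(not np.array_equal(x.data, y.data) for x, y in zip(a, c))

    def test_within_network_correlation_converges(self):
        """Empirical within-block correlation approaches the target as T grows."""
        cfg = two_block_config(n_timepoints=5000, group_sizes={"NC": 1, "EMCI": 1,
                                                               "LMCI": 0, "AD": 0},
                               seed=21)
        cohort = generate_cohort(cfg)
        emci = next(c for c in cohort if c.stage == "EMCI")
        corr = correlation_matrix(emci.data).values
        assert corr[0, 1] == pytest.approx(0.45, abs=0.03)  # block A at EMCI
        assert corr[2, 3] == pytest.approx(0.38, abs=0.03)  # block B at EMCI

    def test_ar1_preserves_cross_correlation_target(self):
        cfg = two_block_config(n_timepoints=5000, ar1=0.4,
                               group_sizes={"NC": 1, "EMCI": 0, "LMCI": 0, "AD": 0},
                               seed=22)
        nc = generate_cohort(cfg)[0]
        corr = correlation_matrix(nc.data).values
        assert corr[0, 1] == pytest.approx(0.3, abs=0.04)


class TestPartition:
    def test_default_partition_covers_all_rois_once(self):
        part = default_partition(90)
        part.validate_cover(90)
        sizes = {n: len(part.indices(n)) for n in part.networks}
        assert sum(sizes.values()) == 90
        assert set(part.networks) == {"DMN", "ATT", "SUB", "AUD", "VIS", "SEN"}

    def test_partition_file_round_trip(self, tmp_path):
        part = default_partition(30)
        path = write_partition(part, tmp_path / "partition.tsv")
        back = read_partition(path)
        assert back.assignment == part.assignment
        assert back.networks == part.networks

    def test_incomplete_cover_rejected(self):
        part = RSNPartition(networks=("A",), assignment={0: "A", 2: "A"})
        with pytest.raises(ValueError, match="missing"):
            part.validate_cover(3)


class TestCohortIO:
    def test_round_trip_lossless(self, tmp_path):
        cohort = generate_cohort(two_block_config(seed=5))
        manifest = write_cohort(cohort, tmp_path / "cohort")
        back = read_cohort(manifest)
        assert len(back) == len(cohort)
        for orig, rt in zip(cohort, back):
            assert rt.subject_id == orig.subject_id
            assert rt.stage == orig.stage
            assert rt.mmse == orig.mmse
            np.testing.assert_array_equal(rt.data, orig.data)

    def test_empty_cohort_manifest_header_only(self, tmp_path):
        manifest = write_cohort([], tmp_path / "empty")
        lines = manifest.read_text().strip().splitlines()
        assert lines == ["subject_id\tstage\tmmse\tpath"]

    def test_file_count_matches_cohort(self, tmp_path):
        cohort = generate_cohort(two_block_config(seed=6))
        manifest = write_cohort(cohort, tmp_path / "c")
        files = list((tmp_path / "c").glob("*.tsv"))
        assert len(files) == len(cohort) + 1  # subjects + manifest

    def test_duplicate_subject_ids_rejected(self, tmp_path):
        cohort = generate_cohort(two_block_config(seed=7))
        dup = cohort + [cohort[0]]
        with pytest.raises(ValueError, match="duplicate"):
            write_cohort(dup, tmp_path / "dup")
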