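"""Tile/element methylation, sample similarity and hypermethylation calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopcall.annotation_io import TranscriptModel
from stopcall.methylation_summary import (
    call_hypermethylated,
    element_methylation,
    promoters_from_transcripts,
    read_cpg_table,
    sample_similarity,
    tile_matrix,
    tile_methylation,
)
from stopcall.sim_data import MethylomeSimConfig, simulate_methylomes


def _cpgs(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "meth", "unmeth"])


class TestTileMethylation:
    def test_mean_of_three_cpgs(self):
        cpgs = _cpgs(
            [("c1", 100, 5, 0), ("c1", 200, 3, 3), ("c1", 300, 0, 4)]
        )
        (tile,) = tile_methylation(cpgs).to_dict("records")
        assert tile["start"] == 0 and tile["end"] == 1000
        assert tile["n_cpg_used"] == 3
        assert tile["mean_level"] == pytest.approx(0.5)

    def test_two_usable_cpgs_undefined(self):
        cpgs = _cpgs([("c1", 100, 5, 0), ("c1", 200, 5, 0)])
        (tile,) = tile_methylation(cpgs).to_dict("records")
        assert tile["n_cpg_used"] == 2
        assert np.isnan(tile["mean_level"])

    def test_low_coverage_cpg_excluded(self):
        cpgs = _cpgs(
            [("c1", 100, 1, 1), ("c1", 200, 5, 0), ("c1", 300, 5, 0),
             ("c1", 400, 5, 0)]
        )
        (tile,) = tile_methylation(cpgs).to_dict("records")
        assert tile["n_cpg_used"] == 3

    def test_fixed_grid(self):
        cpgs = _cpgs([("c1", 999, 5, 0), ("c1", 1000, 5, 0)])
        tiles = tile_methylation(cpgs)
        assert list(tiles["start"]) == [0, 1000]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tile_methylation(_cpgs([("c1", 1, -1, 3)]))

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [
            ("c1", int(p), int(m), int(u))
            for p, m, u in zip(
                rng.choice(5000, 60, replace=False),
                rng.integers(0, 20, 60),
                rng.integers(0, 20, 60),
            )
        ]
        a = tile_methylation(_cpgs(rows))
        b = tile_methylation(_cpgs(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)


class TestSampleSimilarity:
    def test_hand_computed_three_samples(self):
        # d(a,b)=5, d(a,c)=8, d(b,c)=5 -> sims 1, 0, 1
        levels = pd.DataFrame(
            [[0.0, 0.0], [3.0, 4.0], [0.0, 8.0]],
            index=["a", "b", "c"], columns=["t1", "t2"],
        )
        sim = sample_similarity(levels)
        assert sim.loc["a", "b"] == pytest.approx(1.0)
        assert sim.loc["a", "c"] == pytest.approx(0.0)
        assert sim.loc["b", "c"] == pytest.approx(1.0)

    def test_duplicate_samples_have_similarity_one(self):
        levels = pd.DataFrame(
            [[0.1, 0.2], [0.1, 0.2], [0.9, 0.8]],
            index=["a", "a2", "b"],
        )
        sim = sample_similarity(levels)
        assert sim.loc["a", "a2"] == pytest.approx(1.0)

    def test_most_distant_pair_is_zero(self):
        rng = np.random.default_rng(1)
        levels = pd.DataFrame(rng.random((4, 10)), index=list("abcd"))
        sim = sample_similarity(levels)
        off = sim.values[~np.eye(4, dtype=bool)]
        assert off.min() == pytest.approx(0.0)
        assert off.max() <= 1.0

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        levels = pd.DataFrame(rng.random((5, 8)))
        sim = sample_similarity(levels)
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_nan_tiles_dropped_listwise(self):
        levels = pd.DataFrame(
            [[0.0, np.nan, 1.0], [1.0, 0.5, 1.0], [0.5, 0.2, 0.0]],
            index=list("abc"),
        )
        sim = sample_similarity(levels)  # column 1 ignored
        expect = sample_similarity(levels.drop(columns=[1]))
        pd.testing.assert_frame_equal(sim, expect)

    def test_equal_distances_warns_and_sets_one(self):
        levels = pd.DataFrame([[0.0], [1.0]], index=["a", "b"])
        with pytest.warns(UserWarning):
            sim = sample_similarity(levels)
        assert sim.loc["a", "b"] == 1.0


class TestElementMethylation:
    ELEMENTS = pd.DataFrame(
        [{"element_id": "e1", "contig": "c1", "start": 0, "end": 500}]
    )

    def test_mean_of_element_cpgs(self):
        cpgs = _cpgs(
            [("c1", 10, 5, 0), ("c1", 20, 5, 0), ("c1", 30, 0, 5),
             ("c1", 40, 0, 5)]
        )
        (row,) = element_methylation(cpgs, self.ELEMENTS).to_dict("records")
        assert row["mean_level"] == pytest.approx(0.5)
        assert row["n_cpg_used"] == 4

    def test_no_usable_cpgs_undefined(self):
        cpgs = _cpgs([("c1", 10, 1, 1)])
        (row,) = element_methylation(cpgs, self.ELEMENTS).to_dict("records")
        assert np.isnan(row["mean_level"])

    def test_minus_strand_promoter_centred_on_rightmost(self):
        t = TranscriptModel(
            "t1", "g1", "c1", "-", exons=[(10_000, 12_000)], cds=[(10_000, 12_000)]
        )
        (p,) = promoters_from_transcripts([t]).to_dict("records")
        tss = 12_000 - 1
        assert (p["start"], p["end"]) == (tss - 2000, tss + 2000)

    def test_plus_strand_promoter_centred_on_leftmost(self):
        t = TranscriptModel(
            "t1", "g1", "c1", "+", exons=[(10_000, 12_000)], cds=[(10_000, 12_000)]
        )
        (p,) = promoters_from_transcripts([t]).to_dict("records")
        assert (p["start"], p["end"]) == (8000, 12_000)


class TestHypermethylatedCalls:
    def _reps(self, means, element_id="e1"):
        return [
            pd.DataFrame(
                [{"element_id": element_id, "mean_level": m, "n_cpg_used": 5}]
            )
            for m in means
        ]

    def test_planted_difference_called(self):
        a = self._reps([0.80, 0.83, 0.77])
        b = self._reps([0.10, 0.13, 0.07])
        (row,) = call_hypermethylated(a, b).to_dict("records")
        assert row["is_hyper"]
        assert row["p_value"] < 0.05

    def test_exact_threshold_not_called(self):
        a = self._reps([0.5, 0.5])
        b = self._reps([0.2, 0.2])
        (row,) = call_hypermethylated(a, b).to_dict("records")
        assert row["difference"] == 0.30
        assert not row["is_hyper"]

    def test_identical_groups_not_called(self):
        a = self._reps([0.5, 0.6, 0.4])
        (row,) = call_hypermethylated(a, list(a)).to_dict("records")
        assert not row["is_hyper"]
        assert row["p_value"] == 1.0 or row["p_value"] > 0.05

    def test_zero_variance_equal_means_p_one(self):
        a = self._reps([0.5, 0.5])
        (row,) = call_hypermethylated(a, list(a)).to_dict("records")
        assert row["p_value"] == 1.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            call_hypermethylated(self._reps([0.5]), self._reps([0.1, 0.2]))

    def test_bh_column_present(self):
        a = self._reps([0.8, 0.82, 0.78])
        b = self._reps([0.1, 0.12, 0.08])
        out = call_hypermethylated(a, b)
        assert "p_bh" in out.columns


class TestRecoveryFromSimulatedMethylomes:
    def test_planted_elements_recovered(self):
        cfg = MethylomeSimConfig(n_elements=80)
        group_a, group_b, planted, elements = simulate_methylomes(None, cfg, seed=13)
        ea = [element_methylation(r, elements) for r in group_a]
        eb = [element_methylation(r, elements) for r in group_b]
        calls = call_hypermethylated(ea, eb)
        called = set(calls.loc[calls["is_hyper"], "element_id"])
        sens = len(called & planted) / len(planted)
        null = set(elements["element_id"]) - planted
        fpr = len(called - planted) / len(null)
        assert sens >= 0.9
        assert fpr <= 0.07

    def test_no_delta_no_calls(self):
        cfg = MethylomeSimConfig(n_elements=40, planted_delta=0.0)
        group_a, group_b, planted, elements = simulate_methylomes(None, cfg, seed=14)
        ea = [element_methylation(r, elements) for r in group_a]
        eb = [element_methylation(r, elements) for r in group_b]
        calls = call_hypermethylated(ea, eb)
        assert calls["is_hyper"].sum() <= 2  # alpha-level false calls only

    def test_coverage_floor_respected(self):
        cfg = MethylomeSimConfig(n_elements=10, coverage_floor=5)
        group_a, _, _, _ = simulate_methylomes(None, cfg, seed=15)
        for rep in group_a:
            assert ((rep["meth"] + rep["unmeth"]) >= 5).all()

    def test_seeded_determinism(self):
        cfg = MethylomeSimConfig(n_elements=10)
        a1, b1, p1, _ = simulate_methylomes(None, cfg, seed=16)
        a2, b2, p2, _ = simulate_methylomes(None, cfg, seed=16)
        assert p1 == p2
        for x, y in zip(a1 + b1, a2 + b2):
            pd.testing.assert_frame_equal(x, y)


def test_read_cpg_table(tmp_path):
    p = tmp_path / "cpg.tsv"
    p.write_text("c1\t100\t5\t3\nc1\t200\t0\t7\n")
    df = read_cpg_table(p)
    assert list(df.columns) == ["contig", "pos", "meth", "unmeth"]
    assert len(df) == 2


def test_tile_matrix_stacks_samples():
    cpgs = _cpgs([("c1", 100, 5, 0), ("c1", 200, 5, 0), ("c1", 300, 5, 0)])
    mat = tile_matrix({"s1": cpgs, "s2": cpgs})
    assert mat.shape == (2, 1)
    assert mat.iloc[0, 0] == pytest.approx(1.0)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_similarity_matrix_properties(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 6))
    levels = pd.DataFrame(rng.random((n, 12)))
    sim = sample_similarity(levels)
    vals = sim.values
    assert np.allclose(vals, vals.T)
    assert np.allclose(np.diag(vals), 1.0)
    off = vals[~np.eye(n, dtype=bool)]
    assert (off >= 0).all() and (off <= 1).all()
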