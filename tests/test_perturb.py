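"""Perturbation operators, the surrogate predictor, and the impact screen."""

import numpy as np
import pytest

from chromascope import synthetic
from chromascope.insulation import diamond_insulation
from chromascope.perturb import (
    SurrogateConfig,
    SurrogatePredictor,
    activate_enhancers,
    add_ctcf_peak,
    global_scale,
    impact_score,
    permute_sequence,
    screen,
    silence_region,
    surrogate_predict,
)
from chromascope.tracks import Track


@pytest.fixture
def flat_track():
    return Track("chr1", 0, 1_000, np.full(200, 10.0))


class TestSilenceRegion:
    def test_zero_region_is_identity(self):
        t = Track("chr1", 0, 1_000, np.zeros(50))
        out = silence_region(t, (10_000, 20_000))
        np.testing.assert_array_equal(out.values, t.values)

    def test_full_span_zeroes_everything(self, flat_track):
        out = silence_region(flat_track, (0, flat_track.end))
        assert not out.values.any()

    def test_single_kb_zeroed_exactly(self, flat_track):
        out = silence_region(flat_track, (57_000, 58_000))
        assert out.values[57] == 0
        assert out.values[56] == 10.0 and out.values[58] == 10.0

    def test_idempotent(self, flat_track):
        once = silence_region(flat_track, (5_000, 9_000))
        twice = silence_region(once, (5_000, 9_000))
        np.testing.assert_array_equal(once.values, twice.values)


class TestActivateEnhancers:
    def test_smaller_donor_is_noop(self, flat_track):
        donor = Track("chr1", 0, 1_000, np.full(200, 3.0))
        out = activate_enhancers(flat_track, [(0, 200_000)], donor=donor)
        np.testing.assert_array_equal(out.values, flat_track.values)

    def test_fold_one_is_identity(self, flat_track):
        out = activate_enhancers(flat_track, [(10_000, 20_000)], mode="fold",
                                 fold=1.0)
        np.testing.assert_array_equal(out.values, flat_track.values)

    def test_fold_1p1_scales_region_only(self, flat_track):
        out = activate_enhancers(flat_track, [(10_000, 20_000)], mode="fold",
                                 fold=1.1)
        np.testing.assert_allclose(out.values[10:20], 11.0)
        np.testing.assert_allclose(out.values[20:], 10.0)

    def test_replace_if_greater_idempotent(self, flat_track):
        donor = Track("chr1", 0, 1_000, np.full(200, 50.0))
        once = activate_enhancers(flat_track, [(0, 50_000)], donor=donor)
        twice = activate_enhancers(once, [(0, 50_000)], donor=donor)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_nonpositive_fold_rejected(self, flat_track):
        with pytest.raises(ValueError):
            activate_enhancers(flat_track, [(0, 1_000)], mode="fold", fold=0.0)


class TestAddCtcfPeak:
    def test_apex_and_support_width(self):
        t = Track("chr1", 0, 1, np.zeros(400))
        out = add_ctcf_peak(t, (190, 209))       # motif length 19
        nz = np.flatnonzero(out.values)
        assert nz.size <= 79 and nz.size >= 77   # support = 19 + 2*30
        apex = out.values.max()
        assert apex == pytest.approx(1000.0, rel=1e-3)

    def test_max_rule_keeps_larger_original(self):
        v = np.zeros(400)
        v[195:205] = 2000.0
        t = Track("chr1", 0, 1, v)
        out = add_ctcf_peak(t, (190, 209))
        assert out.values[199] == 2000.0

    def test_gaussian_decays_from_apex(self):
        t = Track("chr1", 0, 1, np.zeros(400))
        out = add_ctcf_peak(t, (190, 209))
        mid = int(np.argmax(out.values))
        left = out.values[mid - 35]
        assert 0 < left < out.values[mid - 10] < out.values[mid]


class TestPermuteSequence:
    def test_composition_preserved(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        out = permute_sequence(seq, (40, 136), seed=3)
        assert len(out) == len(seq)
        assert sorted(out) == sorted(seq)
        assert out[:40] == seq[:40] and out[136:] == seq[136:]

    def test_same_seed_reproducible(self):
        seq = "ACGT" * 50
        assert permute_sequence(seq, (0, 160), seed=9) == \
            permute_sequence(seq, (0, 160), seed=9)

    def test_32bp_region_two_orderings(self):
        seq = "A" * 16 + "C" * 16
        outs = {permute_sequence(seq, (0, 32), seed=s) for s in range(20)}
        assert outs <= {"A" * 16 + "C" * 16, "C" * 16 + "A" * 16}
        assert len(outs) == 2

    def test_trailing_remainder_in_place(self):
        seq = "A" * 16 + "C" * 16 + "GGGG"
        out = permute_sequence(seq, (0, 36), seed=1)
        assert out[32:36] == "GGGG"


class TestGlobalScale:
    def test_fold_roundtrip(self, flat_track):
        out = global_scale(global_scale(flat_track, 2.0), 0.5)
        np.testing.assert_allclose(out.values, flat_track.values)

    def test_fold_1p1(self, flat_track):
        np.testing.assert_allclose(global_scale(flat_track, 1.1).values, 11.0)

    def test_nonpositive_rejected(self, flat_track):
        with pytest.raises(ValueError):
            global_scale(flat_track, -1.0)


def _tracks(n_kb=640, step=1_000):
    z = np.zeros(n_kb)
    return {"atac": Track("chr1", 0, step, z.copy()),
            "ctcf": Track("chr1", 0, step, z.copy())}


class TestSurrogatePredict:
    def test_zero_tracks_zero_matrix(self):
        lf = surrogate_predict(_tracks(), ("chr1", 0, 640_000), 10_000)
        assert not lf.values.any()

    def test_deterministic(self):
        t = synthetic.make_truth(seed=2)
        tr = synthetic.make_tracks(t)
        a = surrogate_predict(tr, ("chr1", 0, 1_600_000), 25_000)
        b = surrogate_predict(tr, ("chr1", 0, 1_600_000), 25_000)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_boundary_peaks_insulation_at_center(self):
        tr = _tracks()
        tr["ctcf"].values[320] = 5.0          # lone CTCF site: a boundary
        lf = surrogate_predict(tr, ("chr1", 0, 640_000), 10_000)
        track = diamond_insulation(lf, window_bins=8)
        assert np.nanargmin(track) == 32

    def test_window_not_divisible_rejected(self):
        with pytest.raises(ValueError):
            surrogate_predict(_tracks(), ("chr1", 0, 641_000), 10_000)

    def test_anchor_pair_makes_loop_bump(self):
        tr = _tracks()
        for kb in (100, 300):
            tr["ctcf"].values[kb] = 5.0
            tr["atac"].values[kb] = 5.0
        lf = surrogate_predict(tr, ("chr1", 0, 640_000), 10_000)
        assert lf.values[10, 30] == lf.values.max()


class TestImpactScore:
    def test_identical_is_zero(self):
        t = synthetic.make_truth(seed=0)
        lf = synthetic.render_logfold(t)
        assert impact_score(lf, lf) == 0.0

    def test_single_entry_difference(self):
        t = synthetic.make_truth(synthetic.SimConfig(n_bins=16, n_tads=2,
                                                     tads_per_block=2,
                                                     loop_valencies=()), seed=0)
        a = synthetic.render_logfold(t)
        b = synthetic.render_logfold(t)
        b.values[3, 7] += 0.8
        assert impact_score(a, b) == pytest.approx(0.8 / 256)

    def test_symmetric_in_arguments(self):
        t = synthetic.make_truth(seed=1)
        a = synthetic.render_logfold(t)
        b = synthetic.render_logfold(t)
        b.values += np.linspace(0, 0.1, b.n_bins)[:, None]
        assert impact_score(a, b) == impact_score(b, a)


class TestScreen:
    def test_his_is_exactly_top_decile(self):
        t = synthetic.make_truth(seed=3)
        tr = synthetic.make_tracks(t)
        res = screen(SurrogatePredictor(), tr, ("chr1", 0, 100_000),
                     scales=[256_000])
        assert len(res.table) == 100
        assert int(res.table["his@256000"].sum()) == 10

    def test_all_zero_atac_zero_impacts_deterministic_his(self):
        tr = _tracks(100)
        res = screen(SurrogatePredictor(), tr, ("chr1", 0, 100_000),
                     scales=[64_000])
        assert (res.table["impact@64000"] == 0).all()
        # ties broken by coordinate: the first ten fragments
        assert list(res.table[res.table["his@64000"]]["start"]) == \
            list(range(0, 10_000, 1_000))

    def test_anchor_peak_fragments_rank_first_at_smallest_scale(self):
        """Silencing the 1-kb ATAC peak under a loop anchor outranks
        silencing plateau fragments, across 20 generator seeds."""
        for seed in range(20):
            t = synthetic.make_truth(seed=seed)
            tr = synthetic.make_tracks(t)
            peaks = {int(a) * 25_000 + 12_000 for a in t.anchor_bins()[:4]}
            res = screen(SurrogatePredictor(), tr, ("chr1", 0, 304_000),
                         fragment_size=1_000, scales=[256_000])
            tab = res.table.sort_values("impact@256000", ascending=False)
            assert tab.iloc[0]["start"] in peaks

    def test_screen_pure_function_of_inputs(self):
        t = synthetic.make_truth(seed=4)
        tr = synthetic.make_tracks(t)
        r1 = screen(SurrogatePredictor(), tr, ("chr1", 0, 50_000), scales=[64_000])
        r2 = screen(SurrogatePredictor(), tr, ("chr1", 0, 50_000), scales=[64_000])
        assert r1.table.equals(r2.table)

    def test_category_fractions_sum_to_one(self):
        import pandas as pd

        t = synthetic.make_truth(seed=5)
        tr = synthetic.make_tracks(t)
        cats = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(0, 100_000, 1_000),
                             "category": ["promoter", "enhancer"] * 50})
        res = screen(SurrogatePredictor(), tr, ("chr1", 0, 100_000),
                     scales=[256_000], categories=cats)
        assert res.category_fractions(256_000).sum() == pytest.approx(1.0)


def test_perturbation_outside_window_has_no_effect():
    """Surrogate locality: edits beyond the prediction window change nothing."""
    t = synthetic.make_truth(seed=6)
    tr = synthetic.make_tracks(t)
    window = ("chr1", 0, 1_600_000)
    base = surrogate_predict(tr, window, 25_000)
    edited = dict(tr)
    edited["atac"] = silence_region(tr["atac"], (3_000_000, 3_200_000))
    pert = surrogate_predict(edited, window, 25_000)
    assert impact_score(base, pert) == 0.0
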