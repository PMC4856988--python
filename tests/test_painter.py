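"""Annotation painting: 90 bp rule, GC windows, threshold calibration,
synthetic tracks, toy fiber patterns."""

import numpy as np
import pandas as pd
import pytest

from chromobridge.fiber import FiberSpec
from chromobridge.painter import (GCTrack, PaintConfig, StateTrack,
                                  TrackGapError, calibrate_gc_threshold,
                                  gc_fraction_windows, paint_beads,
                                  paint_to_fiber, read_color_table,
                                  synthesize_annotation, synthesize_sequence,
                                  toy_fiber, write_color_table)


def track_for(rows):
    return StateTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


def full_cover(rows, chrom="chr1", end=10_000):
    """Add background state 7 filler so the track covers [0, end)."""
    rows = sorted(rows, key=lambda r: r[1])
    out, cursor = [], 0
    for c, s, e, st in rows:
        if s > cursor:
            out.append((chrom, cursor, s, 7))
        out.append((c, s, e, st))
        cursor = max(cursor, e)
    if cursor < end:
        out.append((chrom, cursor, end, 7))
    return track_for(out)


CFG1K = PaintConfig(bead_bp=1000)


class TestPaintRules:
    def test_100bp_active_promoter_paints_pink(self):
        t = full_cover([("chr1", 200, 300, 1)])
        colors = paint_beads(t, None, CFG1K, "chr1", 0, 1)
        assert colors[0] == frozenset({"pink"})

    def test_89bp_is_below_threshold_paints_blue(self):
        t = full_cover([("chr1", 200, 289, 4)])
        gc = GCTrack(values=np.array([0.50]), bead_bp=1000)
        cfg = PaintConfig(bead_bp=1000, gc_threshold=0.418)
        colors = paint_beads(t, gc, cfg, "chr1", 0, 1)
        assert colors[0] == frozenset({"blue"})

    def test_3kbp_bead_elongation_plus_low_gc_is_green_and_gray(self):
        cfg = PaintConfig(bead_bp=3000, gc_threshold=0.484)
        t = full_cover([("chr1", 100, 300, 9)])
        gc = GCTrack(values=np.array([0.40]), bead_bp=3000)
        colors = paint_beads(t, gc, cfg, "chr1", 0, 1)
        assert colors[0] == frozenset({"lightgreen", "gray"})

    def test_gc_exactly_at_threshold_is_not_gray(self):
        # the threshold is strict "<"
        cfg = PaintConfig(bead_bp=1000, gc_threshold=0.418)
        t = full_cover([])
        gc = GCTrack(values=np.array([0.418]), bead_bp=1000)
        colors = paint_beads(t, gc, cfg, "chr1", 0, 1)
        assert colors[0] == frozenset({"blue"})

    def test_state13_fallback_without_gc(self):
        t = full_cover([("chr1", 0, 1000, 13)])
        colors = paint_beads(t, None, CFG1K, "chr1", 0, 1)
        assert colors[0] == frozenset({"gray"})

    def test_split_interval_never_changes_color(self):
        # one 100 bp mark vs two abutting 50 bp marks: identical painting
        whole = full_cover([("chr1", 200, 300, 1)])
        split = full_cover([("chr1", 200, 250, 1), ("chr1", 250, 300, 1)])
        for mode in ("pooled", "contiguous"):
            cfg = PaintConfig(bead_bp=1000, overlap_mode=mode)
            assert paint_beads(whole, None, cfg, "chr1", 0, 1) == \
                paint_beads(split, None, cfg, "chr1", 0, 1)

    def test_pooled_vs_contiguous_disagree_on_fragmented_marks(self):
        # two separated 50 bp state-1 marks: pooled sums to 100 >= 90,
        # contiguous sees two 50 bp runs only
        t = full_cover([("chr1", 100, 150, 1), ("chr1", 600, 650, 1)])
        pooled = paint_beads(t, None, PaintConfig(bead_bp=1000), "chr1", 0, 1)
        contig = paint_beads(
            t, None, PaintConfig(bead_bp=1000, overlap_mode="contiguous"),
            "chr1", 0, 1)
        assert pooled[0] == frozenset({"pink"})
        assert contig[0] == frozenset({"blue"})

    def test_gap_in_track_raises(self):
        t = track_for([("chr1", 0, 500, 1)])  # covers only half the bead
        with pytest.raises(TrackGapError):
            paint_beads(t, None, CFG1K, "chr1", 0, 1)

    def test_painting_is_idempotent_under_normalization(self):
        rows = [("chr1", 200, 300, 1), ("chr1", 250, 350, 1),
                ("chr1", 3000, 3200, 9)]
        t = full_cover(rows)
        assert paint_beads(t, None, CFG1K, "chr1", 0, 5) == \
            paint_beads(t.normalized(), None, CFG1K, "chr1", 0, 5)


class TestGCWindows:
    def test_all_gc(self):
        gc = gc_fraction_windows("GCGC" * 250, 1000)
        assert gc.values[0] == 1.0

    def test_equal_composition(self):
        gc = gc_fraction_windows("ACGT" * 250, 1000)
        assert gc.values[0] == 0.5

    def test_418_gc_in_1kbp(self):
        seq = "G" * 418 + "A" * 582
        gc = gc_fraction_windows(seq, 1000)
        assert gc.values[0] == pytest.approx(0.418)
        cfg = PaintConfig(bead_bp=1000, gc_threshold=0.418)
        colors = paint_beads(full_cover([]), gc, cfg, "chr1", 0, 1)
        assert "gray" not in colors[0]

    def test_n_runs_excluded_from_denominator(self):
        seq = "G" * 100 + "N" * 800 + "A" * 100
        gc = gc_fraction_windows(seq, 1000)
        assert gc.values[0] == pytest.approx(0.5)
        assert gc.n_fraction[0] == pytest.approx(0.8)

    def test_all_n_bead_flagged(self):
        gc = gc_fraction_windows("N" * 1000, 1000)
        assert np.isnan(gc.values[0])

    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError):
            gc_fraction_windows("ACGX" * 250, 1000)


class TestCalibration:
    def test_threshold_recovers_state13_fraction_exactly(self):
        rng = np.random.default_rng(0)
        n = 200
        gc_vals = rng.permutation(np.linspace(0.3, 0.6, n))  # distinct
        rows = [("chr1", b * 1000, (b + 1) * 1000, 13)
                for b in range(n) if b % 10 < 3]  # 30% of beads
        t = full_cover(rows, end=n * 1000)
        gc = GCTrack(values=gc_vals, bead_bp=1000)
        thr = calibrate_gc_threshold(gc, t, CFG1K, "chr1", 0)
        assert (gc_vals < thr).mean() == pytest.approx(0.30)

    def test_no_state13_gives_no_gray(self):
        n = 50
        gc = GCTrack(values=np.linspace(0.3, 0.6, n), bead_bp=1000)
        t = full_cover([], end=n * 1000)
        thr = calibrate_gc_threshold(gc, t, CFG1K, "chr1", 0)
        assert (gc.values < thr).sum() == 0

    def test_degenerate_gc_rejected(self):
        gc = GCTrack(values=np.full(10, 0.5), bead_bp=1000)
        t = full_cover([], end=10_000)
        with pytest.raises(ValueError):
            calibrate_gc_threshold(gc, t, CFG1K, "chr1", 0)


class TestSynthesis:
    def test_requested_fractions_realized_within_1_percent(self):
        track, gc = synthesize_annotation(
            region_bp=2_000_000, bead_bp=1000, seed=5,
            pink_fraction=0.04, green_fraction=0.06, het_fraction=0.3)
        cfg = PaintConfig(bead_bp=1000)  # state-13 mode
        colors = paint_beads(track, None, cfg, "chrS", 0, 2000)
        frac = lambda c: np.mean([c in cs for cs in colors])
        assert frac("pink") == pytest.approx(0.04, abs=0.01)
        assert frac("lightgreen") == pytest.approx(0.06, abs=0.01)
        assert frac("gray") == pytest.approx(0.30, abs=0.01)

    def test_zero_proportions_paint_all_blue(self):
        track, _ = synthesize_annotation(
            region_bp=100_000, bead_bp=1000, seed=1,
            pink_fraction=0.0, green_fraction=0.0, het_fraction=0.0)
        colors = paint_beads(track, None, CFG1K, "chrS", 0, 100)
        assert all(cs == frozenset({"blue"}) for cs in colors)

    def test_deterministic_under_seed(self):
        a = synthesize_annotation(500_000, 1000, seed=9)
        b = synthesize_annotation(500_000, 1000, seed=9)
        pd.testing.assert_frame_equal(a[0].intervals, b[0].intervals)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_sequence_roundtrip_recovers_gc(self):
        _, gc = synthesize_annotation(200_000, 1000, seed=3)
        seq = synthesize_sequence(gc, seed=4)
        back = gc_fraction_windows(seq, 1000)
        np.testing.assert_allclose(back.values, gc.values, atol=0.5 / 1000 + 1e-9)

    def test_calibration_on_synthetic_region(self):
        # GC thresholding recovers (approximately) the state-13 gray set
        track, gc = synthesize_annotation(1_000_000, 1000, seed=7,
                                          het_fraction=0.25)
        thr = calibrate_gc_threshold(gc, track, CFG1K, "chrS", 0)
        cfg = PaintConfig(bead_bp=1000, gc_threshold=thr)
        by_gc = paint_beads(track, gc, cfg, "chrS", 0, 1000)
        gray_frac = np.mean(["gray" in cs for cs in by_gc])
        assert gray_frac == pytest.approx(0.25, abs=0.01)


class TestToyFiber:
    def test_regular_spacing_matches_fig1(self):
        f = toy_fiber("regular", 5000, spacing=20)
        pink = f.beads_with_color("pink")
        assert len(pink) == 250
        np.testing.assert_array_equal(pink[:3], [19, 39, 59])

    def test_blocks_pattern(self):
        f = toy_fiber("blocks", 5000, blocks=[(300, "lightgreen"), (100, "pink")])
        assert all("lightgreen" in f.colors[i] for i in range(300))
        assert all("pink" in f.colors[i] for i in range(300, 400))
        assert "lightgreen" in f.colors[400]

    def test_desert_blocks_contain_regular_binding_sites(self):
        f = toy_fiber("blocks", 1000, spacing=20,
                      blocks=[(400, "binding"), (100, "gray")])
        pink = f.beads_with_color("pink")
        assert len(pink) == 2 * 20  # 20 per 400-bead block
        assert len(f.beads_with_color("gray")) == 200

    def test_poisson_matches_regular_density(self):
        f = toy_fiber("poisson", 20000, rate=1 / 20, seed=11)
        n = len(f.beads_with_color("pink"))
        assert abs(n - 1000) < 4 * np.sqrt(1000)
        g = toy_fiber("poisson", 20000, rate=1 / 20, seed=11)
        assert f.colors == g.colors  # same seed -> identical

    def test_multicolor_bead_preserved_into_fiberspec(self):
        colors = [frozenset({"pink", "gray"})] + [frozenset({"blue"})] * 9
        fib = paint_to_fiber(colors, "chr1", 0, 1000)
        assert fib.colors[0] == frozenset({"pink", "gray"})
        assert 0 in fib.beads_with_color("pink")
        assert 0 in fib.beads_with_color("gray")


def test_color_table_roundtrip(tmp_path):
    colors = [frozenset({"pink"}), frozenset({"blue"}),
              frozenset({"gray", "lightgreen"})]
    p = tmp_path / "colors.tsv"
    write_color_table(colors, str(p), "chr1", 1000, 1000)
    back, chrom, start, bead_bp = read_color_table(str(p))
    assert back == colors
    assert (chrom, start, bead_bp) == ("chr1", 1000, 1000)


def test_bed_dialects(tmp_path):
    p = tmp_path / "t.bed"
    p.write_text("chr1\t0\t100\t1_Active_Promoter\n"
                 "chr1\t100\t300\t13\n")
    t = StateTrack.from_bed(str(p))
    assert list(t.intervals["state"]) == [1, 13]


def test_painted_fiber_drives_both_protein_species():
    """End-to-end: synthetic annotation -> painted fiber -> engine, with a
    pink+gray bead binding both the factor and the heterochromatin protein."""
    from chromobridge.engine import SimulationConfig, System
    from chromobridge.fiber import FactorSpecies

    track, gc = synthesize_annotation(200_000, 1000, seed=21,
                                      pink_fraction=0.05, green_fraction=0.05,
                                      het_fraction=0.3)
    thr = calibrate_gc_threshold(gc, track, CFG1K, "chrS", 0)
    cfg = PaintConfig(bead_bp=1000, gc_threshold=thr)
    colors = paint_beads(track, gc, cfg, "chrS", 0, 200)
    # ensure at least one multi-color (pink+gray) bead is present
    colors = list(colors)
    colors[7] = frozenset({"pink", "gray"})
    fib = paint_to_fiber(colors, "chrS", 0, 1000)
    red = FactorSpecies(color="red", count=3,
                        affinity={"pink": 8.0, "lightgreen": 4.0},
                        activation_time=0.0)
    black = FactorSpecies(color="black", count=6, affinity={"gray": 6.0},
                          activation_time=0.0)
    sim = SimulationConfig(fibers=[fib], species=[red, black], box_edge=30.0,
                           run_time=0.0, seed=5)
    sys_ = System(sim)
    # the multi-color bead attracts both species at its per-color strengths
    assert sys_.eps_full[0, 7] == 8.0   # red sees pink
    assert sys_.eps_full[1, 7] == 6.0   # black sees gray
    st = sys_.initial_state(seed=5)
    sys_.step(st, n_steps=200)
    assert np.isfinite(st.positions).all()
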