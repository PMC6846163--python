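"""Centre-location machinery: backgrounds, constructs, calls, histograms."""

import numpy as np
import pytest
from scipy.stats import chisquare

from nucleoscore.location import (
    CentreCall,
    Segment,
    build_construct,
    call_centres,
    gc_matched_background,
    read_nucleosome_set,
    score_histogram,
    synthetic_nucleosome_set,
)
from nucleoscore.location import TestConstruct as Construct
from nucleoscore.profiler import NUCLEOSOME_WINDOW, Profile
from nucleoscore.transforms import gc_content, write_fasta


def flat_profile_with(construct_len, planted: dict[int, float], fill=0.5):
    """Window-147 profile over a construct with chosen values at chosen
    construct positions (positions are window centres)."""
    n = construct_len - NUCLEOSOME_WINDOW + 1
    values = np.full(n, fill)
    for pos, val in planted.items():
        values[pos - 73] = val
    return Profile(values, "construct", 0, NUCLEOSOME_WINDOW, 1, spec_label="bdm")


class TestBackgrounds:
    def test_gc_zero_uses_only_weak_bases(self):
        seq = gc_matched_background(0.0, 147, seed=1)
        assert set(seq.symbols) <= {"A", "T"}

    def test_gc_one_uses_only_strong_bases(self):
        seq = gc_matched_background(1.0, 147, seed=1)
        assert set(seq.symbols) <= {"G", "C"}

    def test_mean_gc_concentrates_on_target(self):
        gcs = [gc_content(gc_matched_background(0.5, 147, seed=s)) for s in range(1000)]
        assert 0.49 <= np.mean(gcs) <= 0.51

    def test_seeded_determinism(self):
        assert (
            gc_matched_background(0.3, 147, seed=7).symbols
            == gc_matched_background(0.3, 147, seed=7).symbols
        )


class TestConstructBuilding:
    def test_fourteen_nucs_sixteen_backgrounds_thirty_segments(self):
        construct = build_construct(synthetic_nucleosome_set(0), 16, seed=0)
        assert len(construct.segments) == 30
        kinds = [s.kind for s in construct.segments]
        assert kinds.count("nucleosomal") == 14
        assert kinds.count("background") == 16

    def test_segments_tile_exactly(self):
        construct = build_construct(synthetic_nucleosome_set(1), 16, seed=3)
        pos = 0
        for seg in construct.segments:
            assert seg.start == pos
            pos = seg.end
        assert pos == len(construct.sequence)

    def test_same_seed_reproduces_construct(self):
        a = build_construct(synthetic_nucleosome_set(2), 16, seed=9)
        b = build_construct(synthetic_nucleosome_set(2), 16, seed=9)
        assert a.sequence.symbols == b.sequence.symbols
        assert a.segments == b.segments

    def test_background_gc_matches_left_neighbour_in_expectation(self):
        diffs = []
        for seed in range(20):
            nucs = synthetic_nucleosome_set(seed)
            construct = build_construct(nucs, 16, seed=seed)
            seq = construct.sequence
            for i, seg in enumerate(construct.segments):
                if seg.kind != "background":
                    continue
                bg_gc = gc_content(seq.subsequence(seg.start, seg.end))
                diffs.append(abs(bg_gc - seg.target_gc))
        assert np.mean(diffs) < 0.05


class TestCentreCalls:
    def test_unique_planted_minimum_is_hit_exactly(self):
        construct = build_construct(synthetic_nucleosome_set(3), 16, seed=3)
        seg = construct.nucleosomal()[0]
        truth = seg.true_centre
        p = flat_profile_with(len(construct.sequence), {truth: 0.0})
        calls = call_centres(construct, p, mode="min")
        call = next(c for c in calls if c.segment == seg.name)
        assert call.called_position == truth and call.distance_to_truth == 0
        assert call.within_window

    def test_minmax_takes_the_closer_extremum(self):
        construct = build_construct(synthetic_nucleosome_set(4), 16, seed=4)
        seg = construct.nucleosomal()[0]
        truth = seg.true_centre
        # minimum far from truth, maximum exactly on it
        p = flat_profile_with(
            len(construct.sequence), {truth: 1.0, seg.start + 2: 0.0}
        )
        call = next(
            c
            for c in call_centres(construct, p, mode="minmax")
            if c.segment == seg.name
        )
        assert call.called_position == truth and call.distance_to_truth == 0

    def test_far_call_reported_outside_window(self):
        segs = [
            Segment("background", "bgL", 0, 300),
            Segment("nucleosomal", "nuc", 300, 600, true_centre=320),
            Segment("background", "bgR", 600, 900),
        ]
        from nucleoscore.fixtures import iid_dna

        construct = Construct(iid_dna(900, seed=5), segs, 5)
        p = flat_profile_with(900, {598: 0.0})  # 278 nt away from truth
        call = call_centres(construct, p, mode="min")[0]
        assert call.distance_to_truth > 73 and not call.within_window

    def test_one_call_per_nucleosomal_segment(self):
        construct = build_construct(synthetic_nucleosome_set(6), 16, seed=6)
        p = flat_profile_with(len(construct.sequence), {200: 0.1})
        calls = call_centres(construct, p, mode="min")
        assert len(calls) == 14
        assert len({c.segment for c in calls}) == 14


class TestScoreHistogram:
    def test_counts_conserve_non_missing_values(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=500)
        v[10] = np.nan
        p = Profile(v, "x", 0, 147, 1, spec_label="bdm", normalized=True)
        h = score_histogram(p)
        assert h.counts.sum() == 499
        assert len(h.counts) == 20

    def test_constant_profile_occupies_one_bin(self):
        p = Profile(np.full(100, 0.5), "x", 0, 147, 1, spec_label="gc", normalized=True)
        h = score_histogram(p)
        assert (h.counts > 0).sum() == 1

    def test_uniform_profile_is_roughly_flat(self):
        rng = np.random.default_rng(1)
        p = Profile(rng.uniform(size=4000), "x", 0, 147, 1, spec_label="gc", normalized=True)
        h = score_histogram(p)
        stat, pval = chisquare(h.counts)
        assert pval > 1e-4

    def test_reference_moments_come_from_companion_profile(self):
        rng = np.random.default_rng(2)
        p = Profile(rng.uniform(size=1000), "x", 0, 147, 1, spec_label="bdm")
        ref = Profile(np.full(1000, 0.25), "x", 0, 147, 1, spec_label="gc")
        h = score_histogram(p, reference=ref)
        assert np.isnan(h.departure)  # zero-sd reference flagged, not faked


class TestNucleosomeSetIO:
    def test_fasta_and_dyads_roundtrip(self, tmp_path):
        nucs = synthetic_nucleosome_set(7)
        fasta = tmp_path / "nucs.fa"
        write_fasta([r.sequence for r in nucs.records], fasta)
        dyads = tmp_path / "dyads.tsv"
        lines = [
            f"{r.name}\t{r.dyad_offset + 1}"
            for r in nucs.records
            if r.dyad_offset is not None
        ]
        dyads.write_text("\n".join(lines) + "\n")
        loaded = read_nucleosome_set(fasta, dyads)
        assert len(loaded) == 14
        for orig, back in zip(nucs.records, loaded.records):
            assert back.sequence.symbols == orig.sequence.symbols
            assert back.dyad_offset == orig.dyad_offset

    def test_synthetic_set_is_labelled_and_mixed(self):
        nucs = synthetic_nucleosome_set(8)
        assert all(r.name.startswith("syn_") for r in nucs.records)
        dyads = [r.dyad_offset for r in nucs.records]
        assert any(d is None for d in dyads) and any(d is not None for d in dyads)
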