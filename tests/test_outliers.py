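"""Z-score tracks, consecutive-window region calling and enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

import anemonepg as apg
from anemonepg.outliers import DegenerateTrackError, genes_in_regions


def _track_frame(values, contig="c", step=10, flagged=None):
    n = len(values)
    return pd.DataFrame({
        "contig": contig,
        "start": np.arange(1, 1 + n * step, step)[:n],
        "end": np.arange(step, step * (n + 1), step)[:n],
        "stat": values,
        "flagged": flagged if flagged is not None else [False] * n,
    })


class TestZScore:
    def test_hand_computed_moments_under_sample_sd(self):
        track = apg.zscore_windows(_track_frame([1.0, 1.0, 1.0, 3.0]), "stat")
        assert track.mean == pytest.approx(1.5)
        assert track.sd == pytest.approx(1.0)  # sample SD, n-1 denominator
        assert track.windows.z.iloc[-1] == pytest.approx(1.5)

    def test_constant_track_is_degenerate(self):
        with pytest.raises(DegenerateTrackError):
            apg.zscore_windows(_track_frame([2.0] * 5), "stat")

    def test_flagged_and_missing_windows_carry_no_z(self):
        df = _track_frame([1.0, 2.0, np.nan, 9.0],
                          flagged=[False, False, False, True])
        track = apg.zscore_windows(df, "stat")
        assert np.isnan(track.windows.z.iloc[2])
        assert np.isnan(track.windows.z.iloc[3])
        assert track.mean == pytest.approx(1.5)  # only the two usable windows

    def test_planted_block_has_top_z(self, rng):
        vals = rng.normal(0, 1, 200)
        vals[80:90] += 25.0
        track = apg.zscore_windows(_track_frame(list(vals)), "stat")
        top10 = np.argsort(track.windows.z.to_numpy())[-10:]
        assert sorted(top10) == list(range(80, 90))


def _brute_force_runs(z, step, starts, contigs, threshold, min_consecutive):
    """Independent run-length scan used as the region-calling oracle."""
    regions = []
    run = []
    prev = None
    for i in range(len(z)):
        extreme = not np.isnan(z[i]) and abs(z[i]) > threshold
        direction = 0 if not extreme else (1 if z[i] > 0 else -1)
        joinable = (run and prev is not None and extreme
                    and contigs[i] == contigs[prev]
                    and starts[i] - starts[prev] == step
                    and direction == run[-1][1])
        if not joinable:
            if len(run) >= min_consecutive:
                regions.append((run[0][0], run[-1][0], run[0][1]))
            run = []
        if extreme:
            run.append((i, direction))
            prev = i
        else:
            prev = None
    if len(run) >= min_consecutive:
        regions.append((run[0][0], run[-1][0], run[0][1]))
    return regions


class TestRegionCalling:
    def test_minimal_qualifying_run(self):
        vals = [0, 0, 4, 4, 4, 4, 0, 0, 0.5, 1]
        track = apg.zscore_windows(_track_frame(vals), "stat")
        track.windows["z"] = vals  # treat the values as SD units directly
        regions = apg.call_outlier_regions(track, threshold=3,
                                           min_consecutive=4)
        assert len(regions) == 1
        assert regions[0].n_windows == 4
        assert regions[0].direction == "high"
        assert (regions[0].start, regions[0].end) == (21, 60)

    def test_interrupted_run_is_discarded(self):
        # three extreme windows, a sub-threshold gap, then one more
        vals = [0, 0, 9, 9, 9, 2.9, 9, 0, 0, 1]
        track = apg.zscore_windows(_track_frame(vals), "stat")
        # force a 3-SD threshold on the raw values by scaling z manually
        track.windows["z"] = vals
        assert apg.call_outlier_regions(track, 3, 4) == []

    def test_direction_change_breaks_a_run(self):
        track = apg.zscore_windows(_track_frame([0.0] * 6 + [1] * 4), "stat")
        track.windows["z"] = [4, 4, -4, -4, 4, 4, 0, 0, 0, 0]
        regions = apg.call_outlier_regions(track, 3, 2)
        assert [r.direction for r in regions] == ["high", "low", "high"]

    def test_matches_brute_force_run_scan(self, rng):
        n = 10_000
        z = rng.normal(0, 1.2, n)
        for start, length, sign in ((100, 3, 1), (500, 4, -1), (900, 7, 1)):
            z[start:start + length] = sign * 5.0
        z[rng.choice(n, 50, replace=False)] = np.nan
        df = _track_frame(list(z))
        df.loc[df.index >= n // 2, "contig"] = "c2"  # contig boundary breaks
        track = apg.zscore_windows(df, "stat")
        track.windows["z"] = z  # compare the run logic on identical scores
        regions = apg.call_outlier_regions(track, 3, 4)
        expected = _brute_force_runs(z, 10, df.start.to_numpy(),
                                     df.contig.to_numpy(), 3, 4)
        assert len(regions) == len(expected)
        for r, (i0, i1, direction) in zip(regions, expected):
            assert r.start == df.start[i0] and r.end == df.end[i1]
            assert r.direction == ("high" if direction > 0 else "low")

    def test_lower_min_consecutive_yields_window_superset(self, pipeline):
        track = apg.zscore_windows(pipeline.hw, "h_w", step=10_000)
        default = apg.call_outlier_regions(track, 3, 4)
        loose = apg.call_outlier_regions(track, 3, 1)

        def spans(regs):
            return {(r.contig, r.start, r.end) for r in regs}

        for r in default:
            assert any(l.contig == r.contig and l.start <= r.start
                       and l.end >= r.end for l in loose)
        assert sum(r.n_windows for r in loose) \
            >= sum(r.n_windows for r in default)

    def test_members_recheckable_and_contig_order_invariant(self, pipeline):
        track = apg.zscore_windows(pipeline.diversity, "pi_per_bp",
                                   step=10_000)
        regions = apg.call_outlier_regions(track)
        w = track.windows
        for r in regions:
            members = w[(w.contig == r.contig) & (w.start >= r.start)
                        & (w.end <= r.end)]
            assert (members.z.abs() > 3).all()
        flipped = track.windows.iloc[::-1]
        track2 = apg.ZScoreTrack(track.statistic, flipped, track.mean,
                                 track.sd, track.step)
        again = apg.call_outlier_regions(track2)
        assert {(r.contig, r.start, r.end) for r in again} \
            == {(r.contig, r.start, r.end) for r in regions}


class TestGenesInRegions:
    def test_overlap_including_single_base(self, pipeline, tmp_path):
        import gffutils
        from anemonepg.simulate import write_gff3
        path = tmp_path / "g.gff3"
        write_gff3(pipeline.dataset.reference, path)
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique")
        gene = pipeline.dataset.reference.genes[0]
        g_start = min(s for s, _, _ in gene.cds_segments)
        g_end = max(e for _, e, _ in gene.cds_segments)
        inside = apg.OutlierRegion(gene.contig, g_start - 10, g_end + 10,
                                   "h_w", "high", 4, 5.0)
        one_bp = apg.OutlierRegion(gene.contig, g_end, g_end + 500,
                                   "h_w", "high", 4, 5.0)
        outside = apg.OutlierRegion(gene.contig, g_end + 1, g_end + 500,
                                    "h_w", "high", 4, 5.0)
        per_region, union = genes_in_regions([inside, one_bp, outside], db)
        assert gene.gene_id in per_region[0]
        assert gene.gene_id in per_region[1]
        assert gene.gene_id not in per_region[2]
        assert union.count(gene.gene_id) == 1

    def test_equals_brute_force_interval_intersection(self, pipeline,
                                                      tmp_path, rng):
        import gffutils
        from anemonepg.simulate import write_gff3
        path = tmp_path / "g.gff3"
        write_gff3(pipeline.dataset.reference, path)
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique")
        regions = [apg.OutlierRegion("contig_1", int(s), int(s) + 50_000,
                                     "pi", "high", 4, 4.0)
                   for s in rng.integers(1, 2_500_000, 5)]
        per_region, _ = genes_in_regions(regions, db)
        for idx, r in enumerate(regions):
            expected = [g.gene_id for g in pipeline.dataset.reference.genes
                        if g.contig == r.contig
                        and min(s for s, _, _ in g.cds_segments) <= r.end
                        and max(e for _, e, _ in g.cds_segments) >= r.start]
            assert sorted(per_region[idx]) == sorted(expected)


class TestEnrichment:
    def test_exact_combinatorial_tail(self):
        universe = [f"g{i}" for i in range(20)]
        gene_list = universe[:5]
        term_map = pd.DataFrame({"gene_id": universe[:5], "term_id": "T1"})
        out = apg.enrichment(gene_list, universe, term_map)
        expected = comb(5, 5) * comb(15, 0) / comb(20, 5)
        assert out.p_raw[0] == pytest.approx(expected)
        assert out.p_raw[0] == pytest.approx(1 / 15504)
        # single tested term: BY adjustment is the identity
        assert out.p_adj[0] == pytest.approx(out.p_raw[0])

    def test_planted_term_ranks_first_and_by_is_monotone(self, rng):
        universe = [f"g{i}" for i in range(200)]
        gene_list = list(rng.choice(universe, 30, replace=False))
        rows = []
        for t in range(50):
            members = rng.choice(universe, 20, replace=False)
            rows += [{"gene_id": g, "term_id": f"T{t:02d}"} for g in members]
        rows += [{"gene_id": g, "term_id": "PLANTED"} for g in gene_list[:15]]
        out = apg.enrichment(gene_list, universe, pd.DataFrame(rows))
        assert out.sort_values("p_adj").iloc[0].term_id == "PLANTED"
        ranked = out.sort_values("p_raw")
        assert (np.diff(ranked.p_adj.to_numpy()) >= -1e-12).all()
        assert (out.p_adj >= out.p_raw - 1e-12).all()

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            apg.enrichment(["gX"], ["g1"], pd.DataFrame({
                "gene_id": ["g1"], "term_id": ["T"]}))
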