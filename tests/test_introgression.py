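import math

import numpy as np
import pandas as pd
import pytest

from introtrace.io_formats import GenomeIndex, read_bedgraph
from introtrace.introgression import (
    IntrogressionBlock,
    call_blocks,
    export_tracks,
    scaled_window_params,
    windowed_density,
)
from introtrace.synthetic_data import TrioSimConfig, simulate_trio
from introtrace.trio_origin import TrioOriginTable, classify_trio


def _table(rows):
    return TrioOriginTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "category"]), "i", "d", "r"
    )


def _reciprocal_overlap(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


class TestWindowedDensity:
    def test_empty_table_all_zero(self):
        g = GenomeIndex({"chr1": 10_000})
        track = windowed_density(_table([]), g, window=1000, step=500)
        assert len(track) == math.ceil(10_000 / 500)
        assert (track["n_total"] == 0).all()
        assert track["donor_fraction"].isna().all()

    def test_single_snp_window_multiplicity(self):
        g = GenomeIndex({"chr1": 10_000})
        track = windowed_density(_table([("chr1", 5000, "donor")]), g,
                                 window=1000, step=500)
        # an interior SNP falls in ceil(window/step) = 2 overlapping windows
        assert int((track["n_donor"] > 0).sum()) == 2

    def test_window_step_validation(self):
        g = GenomeIndex({"chr1": 1000})
        with pytest.raises(ValueError):
            windowed_density(_table([]), g, window=100, step=200)

    def test_oversized_window_truncated_with_warning(self):
        g = GenomeIndex({"chr1": 500})
        with pytest.warns(UserWarning, match="truncat"):
            track = windowed_density(_table([]), g, window=1000, step=1000)
        assert track["end"].iloc[0] == 500

    def test_uniform_density_poisson_counts(self):
        lam = 1e-3
        g = GenomeIndex({"chr1": 2_000_000})
        rng = np.random.default_rng(3)
        n = rng.poisson(lam * 2_000_000)
        pos = np.sort(rng.choice(2_000_000, size=n, replace=False) + 1)
        table = _table([("chr1", int(p), "receptor") for p in pos])
        window = 100_000
        track = windowed_density(table, g, window=window, step=window)
        mean = lam * window
        assert (abs(track["n_total"] - mean) < 4 * np.sqrt(mean)).all()


class TestCallBlocks:
    def test_zero_donor_no_blocks(self):
        g = GenomeIndex({"chr1": 100_000})
        table = _table([("chr1", p, "receptor") for p in range(100, 99_000, 100)])
        track = windowed_density(table, g, window=10_000, step=5_000)
        assert call_blocks(track) == []

    def test_planted_segment_recovered(self):
        """A donor segment spanning half a 10 Mb chromosome is recovered with
        >= 90% reciprocal overlap."""
        g = GenomeIndex({"chr1": 10_000_000})
        seg = ("chr1", 2_500_001, 7_500_000)
        cfg = TrioSimConfig(
            genome=g, donor_density=1e-3, receptor_density=1e-3,
            introgression_segments=[seg], unknown_fraction=0.0, het_fraction=0.0,
            seed=31,
        )
        trio = simulate_trio(cfg)
        table = classify_trio(trio.improved, trio.donor, trio.receptor)
        track = windowed_density(table, g, window=500_000, step=250_000)
        blocks = call_blocks(track, table=table)
        donor_blocks = [b for b in blocks if b.source_category == "donor"]
        assert len(donor_blocks) == 1
        b = donor_blocks[0]
        assert _reciprocal_overlap((b.start, b.end), seg[1:]) >= 0.9

    def test_unknown_cluster_called_as_unknown_not_donor(self, default_trio):
        cfg, trio = default_trio
        table = classify_trio(trio.improved, trio.donor, trio.receptor)
        window, step = scaled_window_params(cfg.genome)
        track = windowed_density(table, cfg.genome, window=window, step=step)
        unk = call_blocks(track, category="unknown", table=table)
        assert len(unk) >= 1
        assert all(b.source_category == "unknown" for b in unk)
        donor_blocks = call_blocks(track, category="donor", table=table)
        # no donor block may sit on top of an unknown cluster
        for d in donor_blocks:
            for u in unk:
                assert d.chrom != u.chrom or _reciprocal_overlap(
                    (d.start, d.end), (u.start, u.end)
                ) < 0.5

    def test_monotone_in_min_fraction(self, default_trio):
        cfg, trio = default_trio
        table = classify_trio(trio.improved, trio.donor, trio.receptor)
        window, step = scaled_window_params(cfg.genome)
        track = windowed_density(table, cfg.genome, window=window, step=step)
        prev = None
        for mf in (0.2, 0.5, 0.8):
            blocks = call_blocks(track, min_fraction=mf, table=table)
            if prev is not None:
                assert len(blocks) <= len(prev)
                total = sum(b.length for b in blocks)
                assert total <= sum(b.length for b in prev)
            prev = blocks

    def test_blocks_contain_min_snps_recounted_from_sites(self, default_trio):
        cfg, trio = default_trio
        table = classify_trio(trio.improved, trio.donor, trio.receptor)
        window, step = scaled_window_params(cfg.genome)
        track = windowed_density(table, cfg.genome, window=window, step=step)
        for b in call_blocks(track, min_snps=10, table=table):
            sites = table.sites
            n = (
                (sites["chrom"] == b.chrom)
                & (sites["category"] == b.source_category)
                & (sites["pos"].between(b.start, b.end))
            ).sum()
            assert n == b.n_snps >= 10

    def test_threshold_validation(self):
        g = GenomeIndex({"chr1": 1000})
        track = windowed_density(_table([]), g, window=1000, step=1000)
        with pytest.raises(ValueError):
            call_blocks(track, min_fraction=0)
        with pytest.raises(ValueError):
            call_blocks(track, category="weird")


class TestExport:
    def test_bed_coordinate_conversion(self, tmp_path):
        g = GenomeIndex({"chr2": 1000})
        track = windowed_density(
            _table([("chr2", p, "donor") for p in range(1, 101)]), g,
            window=1000, step=1000,
        )
        block = IntrogressionBlock("chr2", 1, 100, 100, 1.0, "donor")
        bg, bed = tmp_path / "t.bedgraph", tmp_path / "t.bed"
        export_tracks(track, [block], bg, bed)
        lines = [l for l in bed.read_text().splitlines() if not l.startswith("#")]
        assert lines[0].split("\t")[:3] == ["chr2", "0", "100"]

    def test_empty_blocks_header_only_bed(self, tmp_path):
        g = GenomeIndex({"chr1": 1000})
        track = windowed_density(_table([]), g, window=1000, step=1000)
        bed = tmp_path / "e.bed"
        export_tracks(track, [], tmp_path / "e.bedgraph", bed)
        lines = bed.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_bedgraph_round_trip_fractions(self, tmp_path):
        g = GenomeIndex({"chr1": 2000})
        rows = [("chr1", p, "donor") for p in range(1, 900, 10)]
        rows += [("chr1", p, "receptor") for p in range(1001, 2000, 10)]
        track = windowed_density(_table(rows), g, window=1000, step=1000)
        bg = tmp_path / "f.bedgraph"
        export_tracks(track, [], bg, tmp_path / "f.bed")
        back = read_bedgraph(bg)
        nonzero = track[track["n_total"] > 0].reset_index()
        assert np.allclose(back["value"], nonzero["donor_fraction"])
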