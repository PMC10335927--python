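import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcimpute.panel_store import (
    BITS,
    CARRIER_LIST,
    GeneticMap,
    PanelFormatError,
    PanelVersionError,
    VariantSite,
    build_sparse_panel,
    read_binary_panel,
    read_genetic_map,
    write_binary_panel,
)
from lcimpute.sparse_pbwt import PbwtCheckpoints, build_sparse_pbwt

from conftest import panel_from_dense, random_dense_panel


class TestBuildSparsePanel:
    def test_common_site_is_bits(self):
        # MAF 0.5 >= 0.001 forces the bit encoding
        dense = np.zeros((1, 10), dtype=np.uint8)
        dense[0, :5] = 1
        panel = build_sparse_panel(dense, maf_threshold=0.001)
        assert panel.columns[0].encoding == BITS

    def test_singleton_among_many_is_carrier_list(self):
        dense = np.zeros((1, 10_000), dtype=np.uint8)
        dense[0, 4321] = 1  # MAF 1e-4 < 1e-3
        panel = build_sparse_panel(dense, maf_threshold=0.001)
        col = panel.columns[0]
        assert col.encoding == CARRIER_LIST
        assert col.carriers.tolist() == [4321]
        assert col.minor_is_alt

    def test_monomorphic_site_empty_carriers(self):
        panel = build_sparse_panel(np.zeros((1, 10), dtype=np.uint8))
        col = panel.columns[0]
        assert col.encoding == CARRIER_LIST
        assert col.carriers.size == 0

    def test_maf_tie_goes_to_bits(self):
        # MAF exactly at the threshold is common ("MAF >= 0.001")
        dense = np.zeros((1, 1000), dtype=np.uint8)
        dense[0, 0] = 1  # MAF 0.001
        panel = build_sparse_panel(dense, maf_threshold=0.001)
        assert panel.columns[0].encoding == BITS

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_sparse_panel([[0, 1], [0, 1, 1]])

    def test_non_biallelic_rejected_with_site(self):
        with pytest.raises(ValueError, match="site 1"):
            build_sparse_panel([[0, 1], [0, 2]])

    def test_minor_carrier_count_rule(self, rng):
        dense = random_dense_panel(rng, 20, 50)
        panel = build_sparse_panel(dense, maf_threshold=0.3)
        for s, col in enumerate(panel.columns):
            if col.encoding == CARRIER_LIST:
                ac = int(dense[s].sum())
                assert len(col.carriers) == min(ac, 20 - ac)


class TestGetAllele:
    def test_bits_column(self):
        dense = np.zeros((1, 8), dtype=np.uint8)
        dense[0, 3] = dense[0, 5] = dense[0, 6] = dense[0, 7] = 1
        panel = build_sparse_panel(dense)
        assert panel.get_allele(3, 0) == 1
        assert panel.get_allele(0, 0) == 0

    def test_carrier_list_column(self):
        dense = np.zeros((1, 20), dtype=np.uint8)
        dense[0, 7] = 1
        panel = build_sparse_panel(dense, maf_threshold=0.1)
        assert panel.columns[0].encoding == CARRIER_LIST
        assert panel.get_allele(7, 0) == 1
        assert panel.get_allele(0, 0) == 0

    def test_round_trip_identity(self, rng):
        dense = random_dense_panel(rng, 50, 20, rare_fraction=0.5)  # 20 sites x 50 haps
        panel = build_sparse_panel(dense, maf_threshold=0.1)
        for h in range(50):
            for s in range(20):
                assert panel.get_allele(h, s) == dense[s, h]

    def test_out_of_range(self):
        panel = build_sparse_panel([[0, 1]])
        with pytest.raises(IndexError):
            panel.get_allele(2, 0)
        with pytest.raises(IndexError):
            panel.get_allele(0, 1)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_dense_sparse_dense_identity(seed):
    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(2, 24))
    n_site = int(rng.integers(1, 40))
    dense = random_dense_panel(rng, n_hap, n_site, rare_fraction=0.6)
    panel = build_sparse_panel(dense, maf_threshold=0.15)
    np.testing.assert_array_equal(panel.dense(), dense)


def test_transpose_matches_columns(rng):
    dense = random_dense_panel(rng, 30, 80, rare_fraction=0.7)
    panel = build_sparse_panel(dense, maf_threshold=0.1)
    for s, col in enumerate(panel.columns):
        if col.encoding != CARRIER_LIST:
            continue
        for h in range(30):
            in_col = h in col.carriers
            in_tr = s in panel.transpose[h]
            assert in_col == in_tr


def test_storage_cost_accounting(rng):
    dense = random_dense_panel(rng, 16, 40, rare_fraction=0.5)
    panel = build_sparse_panel(dense, maf_threshold=0.2)
    expected = 0
    for s in range(40):
        ac = int(dense[s].sum())
        minor = min(ac, 16 - ac)
        if minor / 16 >= 0.2:
            expected += 2  # 16 bits
        else:
            expected += 4 * minor
    assert panel.storage_cost_bytes() == expected


class TestGeneticMap:
    def test_anchor_value(self):
        gmap = GeneticMap([1000, 2000], [0.0, 0.2])
        assert gmap.interpolate_cm(1000) == 0.0
        assert gmap.interpolate_cm(2000) == pytest.approx(0.2)

    def test_midway_linear(self):
        gmap = GeneticMap([1000, 2000], [0.0, 0.2])
        assert gmap.interpolate_cm(1500) == pytest.approx(0.1)

    def test_extrapolation_below_first_anchor(self):
        gmap = GeneticMap([1000, 2000], [5.0, 5.2], extrapolation_rate_cm_per_mb=1.0)
        # first_cm - gap_bp * 1e-6
        assert gmap.interpolate_cm(0) == pytest.approx(5.0 - 1000 * 1e-6)
        assert gmap.interpolate_cm(3_002_000) == pytest.approx(5.2 + 3.0)

    def test_empty_map_errors(self):
        gmap = GeneticMap([], [])
        with pytest.raises(ValueError, match="empty"):
            gmap.interpolate_cm(100)

    def test_bad_anchors_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap([10, 10], [0.0, 0.1])
        with pytest.raises(ValueError):
            GeneticMap([10, 20], [0.2, 0.1])

    def test_text_round_trip(self, tmp_path):
        path = tmp_path / "m.map"
        with open(path, "w") as fh:
            fh.write("pos rate cM\n1000 1.0 0.001\n2000 1.0 0.002\n")
        gmap = read_genetic_map(path)
        np.testing.assert_array_equal(gmap.pos_bp, [1000, 2000])
        np.testing.assert_allclose(gmap.cm, [0.001, 0.002])


class TestBinaryFormat:
    def _make(self, seed=0, n_hap=50, n_site=200):
        rng = np.random.default_rng(seed)
        dense = random_dense_panel(rng, n_hap, n_site, rare_fraction=0.6)
        panel, gmap = panel_from_dense(dense, maf_threshold=0.1)
        checkpoints = build_sparse_pbwt(panel)
        return panel, checkpoints, gmap

    def test_round_trip_equality(self, tmp_path):
        panel, cps, gmap = self._make()
        path = tmp_path / "p.bin"
        write_binary_panel(panel, cps, gmap, path)
        p2, c2, g2 = read_binary_panel(path)
        assert p2.n_hap == panel.n_hap and p2.n_site == panel.n_site
        assert p2.maf_threshold == panel.maf_threshold
        for a, b in zip(panel.sites, p2.sites):
            assert (a.chrom, a.pos_bp, a.ref, a.alt, a.is_snp, a.alt_count) == (
                b.chrom, b.pos_bp, b.ref, b.alt, b.is_snp, b.alt_count
            )
            assert a.cm == pytest.approx(b.cm, abs=0)
        np.testing.assert_array_equal(panel.dense(), p2.dense())
        for a, b in zip(panel.columns, p2.columns):
            assert a.encoding == b.encoding and a.minor_is_alt == b.minor_is_alt
        np.testing.assert_array_equal(cps.checkpoint_sites, c2.checkpoint_sites)
        for a, b in zip(cps.prefix_arrays, c2.prefix_arrays):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(gmap.pos_bp, g2.pos_bp)
        np.testing.assert_array_equal(gmap.cm, g2.cm)

    def test_write_deterministic(self, tmp_path):
        panel, cps, gmap = self._make(seed=3)
        p1, p2 = tmp_path / "a.bin", tmp_path / "b.bin"
        write_binary_panel(panel, cps, gmap, p1)
        write_binary_panel(panel, cps, gmap, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_corrupted_magic_rejected(self, tmp_path):
        panel, cps, gmap = self._make()
        path = tmp_path / "p.bin"
        write_binary_panel(panel, cps, gmap, path)
        raw = bytearray(path.read_bytes())
        raw[0] = 0x58
        path.write_bytes(bytes(raw))
        with pytest.raises(PanelFormatError, match="magic"):
            read_binary_panel(path)

    def test_version_mismatch_rejected(self, tmp_path):
        panel, cps, gmap = self._make()
        path = tmp_path / "p.bin"
        write_binary_panel(panel, cps, gmap, path)
        raw = bytearray(path.read_bytes())
        raw[4] = 99
        path.write_bytes(bytes(raw))
        with pytest.raises(PanelVersionError):
            read_binary_panel(path)

    def test_truncated_rejected(self, tmp_path):
        panel, cps, gmap = self._make()
        path = tmp_path / "p.bin"
        write_binary_panel(panel, cps, gmap, path)
        path.write_bytes(path.read_bytes()[: len(path.read_bytes()) // 2])
        with pytest.raises(PanelFormatError):
            read_binary_panel(path)

    def test_empty_panel_round_trip(self, tmp_path):
        panel = build_sparse_panel([])
        cps = PbwtCheckpoints(np.empty(0, dtype=np.int64), [])
        gmap = GeneticMap.uniform(1000)
        path = tmp_path / "e.bin"
        write_binary_panel(panel, cps, gmap, path)
        p2, c2, g2 = read_binary_panel(path)
        assert p2.n_site == 0 and len(c2.prefix_arrays) == 0
        np.testing.assert_array_equal(g2.pos_bp, gmap.pos_bp)

    def test_checkpoints_rederivable_from_loaded_panel(self, tmp_path):
        panel, cps, gmap = self._make(seed=9)
        path = tmp_path / "p.bin"
        write_binary_panel(panel, cps, gmap, path)
        p2, c2, _ = read_binary_panel(path)
        fresh = build_sparse_pbwt(p2)
        np.testing.assert_array_equal(fresh.checkpoint_sites, c2.checkpoint_sites)
        for a, b in zip(fresh.prefix_arrays, c2.prefix_arrays):
            np.testing.assert_array_equal(a, b)
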