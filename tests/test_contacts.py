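import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from chromdpd import (
    ContactMap,
    bin_pairs,
    contacts_from_conformation,
    contacts_from_distance_map,
    contacts_per_bead,
    moore_curve,
    sample_bulk_contacts,
    sample_contacts,
    shuffle_contact_map,
)
from chromdpd.conformations import Conformation


def straight_rod(n, spacing=1.0):
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return Conformation(coords, [(0, n)])


class TestContactMapType:
    def test_canonicalization(self):
        cm = ContactMap(5, [(3, 1), (0, 2)])
        np.testing.assert_array_equal(cm.pairs, [[0, 2], [1, 3]])

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            ContactMap(5, [(2, 2)])

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ContactMap(5, [(1, 2), (2, 1)])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            ContactMap(3, [(0, 5)])


class TestContactsFromConformation:
    def test_straight_rod_no_contacts(self):
        cm = contacts_from_conformation(straight_rod(10), 0.5)
        assert cm.n_contacts == 0

    def test_threshold_is_inclusive(self):
        # beads 0 and 2 at exactly r_contact
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 0.0],
                           [0.8, 0.0, 0.0]])
        cm = contacts_from_conformation(Conformation(coords, [(0, 3)]), 0.8)
        assert cm.pair_set() == {(0, 2)}

    def test_backbone_adjacent_excluded(self):
        cm = contacts_from_conformation(straight_rod(5, spacing=0.3), 0.35)
        assert all(j - i > 1 for i, j in cm.pairs)

    def test_matches_brute_force_enumeration(self, moore3=None):
        conf = moore_curve(2)
        cm = contacts_from_conformation(conf, 1.0)
        expected = set()
        for i in range(conf.n_beads):
            for j in range(i + 2, conf.n_beads):
                if np.linalg.norm(conf.coords[i] - conf.coords[j]) <= 1.0:
                    expected.add((i, j))
        assert cm.pair_set() == expected


class TestContactsPerBead:
    def test_empty(self):
        assert contacts_per_bead(ContactMap(100, [])) == 0.0

    def test_definition(self):
        pairs = [(i, i + 2) for i in range(2048)]
        assert contacts_per_bead(ContactMap(4096, pairs)) == 0.5

    def test_monotone_in_radius(self, globule128):
        counts = [
            contacts_from_conformation(globule128, r).n_contacts
            for r in (0.5, 0.65, 0.8, 1.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]


class TestSampleContacts:
    @pytest.fixture
    def cmap1000(self):
        rng = np.random.default_rng(0)
        pairs = set()
        while len(pairs) < 1000:
            i, j = sorted(rng.integers(0, 200, 2))
            if j > i:
                pairs.add((int(i), int(j)))
        return ContactMap(200, sorted(pairs))

    def test_fraction_one_is_identity(self, cmap1000):
        out = sample_contacts(cmap1000, 1.0, seed=3)
        np.testing.assert_array_equal(out.pairs, cmap1000.pairs)

    def test_fraction_zero_is_empty(self, cmap1000):
        assert sample_contacts(cmap1000, 0.0, seed=3).n_contacts == 0

    def test_exact_count_and_marginal_frequency(self, cmap1000):
        first = tuple(cmap1000.pairs[0])
        hits = 0
        n_seeds = 400
        for s in range(n_seeds):
            out = sample_contacts(cmap1000, 0.5, seed=s)
            assert out.n_contacts == 500
            hits += first in out.pair_set()
        # hypergeometric marginal: each pair retained w.p. 0.5
        assert hits / n_seeds == pytest.approx(0.5, abs=0.1)

    def test_subset_of_input(self, cmap1000):
        out = sample_contacts(cmap1000, 0.3, seed=9)
        assert out.pair_set() <= cmap1000.pair_set()


class TestSampleBulkContacts:
    def test_uniform_weights_reduce_to_plain_sampling(self):
        pairs = [(i, i + 2) for i in range(50)]
        cm = ContactMap(60, pairs, multiplicity=np.ones(50, dtype=int))
        out = sample_bulk_contacts(cm, 0.5, max_per_bin=10**6, seed=4)
        assert out.n_contacts == 25
        assert out.pair_set() <= cm.pair_set()

    def test_per_bin_cap_enforced(self):
        rng = np.random.default_rng(1)
        pairs = sorted({(int(a), int(b)) for a, b in
                        (sorted(rng.integers(0, 30, 2)) for _ in range(300))
                        if a != b})
        cm = ContactMap(30, pairs,
                        multiplicity=rng.integers(1, 10, len(pairs)))
        out = sample_bulk_contacts(cm, 0.5, max_per_bin=2, seed=7)
        degree = np.bincount(out.pairs.ravel(), minlength=30)
        assert degree.max() <= 2

    def test_weight_proportional_selection(self):
        cm = ContactMap(6, [(0, 2), (3, 5)],
                        multiplicity=np.array([9, 1]))
        picked_heavy = 0
        n_seeds = 300
        for s in range(n_seeds):
            out = sample_bulk_contacts(cm, 0.1, max_per_bin=2, seed=s)
            assert out.n_contacts == 1
            picked_heavy += (0, 2) in out.pair_set()
        assert picked_heavy / n_seeds == pytest.approx(0.9, abs=0.07)

    def test_requires_multiplicity(self):
        with pytest.raises(ValueError, match="multiplicit"):
            sample_bulk_contacts(ContactMap(5, [(0, 2)]), 0.5)


class TestShuffleContactMap:
    def test_saturated_separation_unchanged(self):
        pairs = [(i, i + 1) for i in range(5)]
        cm = ContactMap(6, pairs)
        out = shuffle_contact_map(cm, seed=0)
        assert out.pair_set() == cm.pair_set()

    def test_separation_histogram_preserved(self):
        rng = np.random.default_rng(2)
        pairs = sorted({(int(a), int(b)) for a, b in
                        (sorted(rng.integers(0, 100, 2)) for _ in range(400))
                        if a != b})
        cm = ContactMap(100, pairs)
        out = shuffle_contact_map(cm, seed=5)
        seps_in = np.bincount(cm.pairs[:, 1] - cm.pairs[:, 0])
        seps_out = np.bincount(out.pairs[:, 1] - out.pairs[:, 0],
                               minlength=len(seps_in))
        np.testing.assert_array_equal(seps_in, seps_out)

    def test_positions_uniform_within_separation(self):
        cm = ContactMap(10, [(0, 3)])  # one pair at separation 3, 7 slots
        counts = np.zeros(7, dtype=int)
        for s in range(700):
            out = shuffle_contact_map(cm, seed=s)
            counts[out.pairs[0, 0]] += 1
        stat, p = chisquare(counts)
        assert p > 1e-3


class TestBinPairs:
    CHROM_SIZES = {"chr1": 1_000_000, "chr2": 600_000}

    def test_floor_binning(self):
        df = pd.DataFrame(
            [("chr1", 150_000, "chr1", 450_000)],
            columns=["chrom1", "pos1", "chrom2", "pos2"],
        )
        cmap, table = bin_pairs(df, self.CHROM_SIZES, 200_000)
        assert cmap.pair_set() == {(0, 2)}
        assert table.n_beads == 5 + 3

    def test_intra_and_adjacent_bin_dropped(self):
        df = pd.DataFrame(
            [
                ("chr1", 10_000, "chr1", 50_000),    # same bin
                ("chr1", 10_000, "chr1", 210_000),   # adjacent bins
            ],
            columns=["chrom1", "pos1", "chrom2", "pos2"],
        )
        cmap, _ = bin_pairs(df, self.CHROM_SIZES, 200_000)
        assert cmap.n_contacts == 0

    def test_hand_enumerated_fixture(self):
        rows = [
            ("chr1", 10_000, "chr1", 450_000),   # (0, 2)
            ("chr1", 460_000, "chr1", 30_000),   # (0, 2) again -> mult 2
            ("chr1", 10_000, "chr1", 850_000),   # (0, 4)
            ("chr2", 10_000, "chr2", 590_000),   # (5, 7)
            ("chr1", 10_000, "chr2", 10_000),    # trans (0, 5)
            ("chr1", 10_000, "chr3", 10_000),    # unknown chrom -> skipped
            ("chr1", 2_000_000, "chr1", 10_000), # out of range -> skipped
            ("chr1", 5_000, "chr1", 199_999),    # same bin -> dropped
            ("chr2", 5_000, "chr2", 210_000),    # adjacent -> dropped
            ("chr1", 999_999, "chr1", 10_000),   # (0, 4)
        ]
        df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
        cmap, table = bin_pairs(df, self.CHROM_SIZES, 200_000)
        assert cmap.pair_set() == {(0, 2), (0, 4), (5, 7), (0, 5)}
        mult = dict(zip(map(tuple, cmap.pairs), cmap.multiplicity))
        assert mult[(0, 2)] == 2 and mult[(0, 4)] == 2
        assert contacts_per_bead(cmap) == pytest.approx(4 / 8)

    def test_trans_drop(self):
        df = pd.DataFrame(
            [("chr1", 10_000, "chr2", 10_000),
             ("chr1", 10_000, "chr1", 450_000)],
            columns=["chrom1", "pos1", "chrom2", "pos2"],
        )
        cmap, _ = bin_pairs(df, self.CHROM_SIZES, 200_000, trans="drop")
        assert cmap.pair_set() == {(0, 2)}

    def test_one_chain_per_chromosome(self):
        df = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
        _, table = bin_pairs(df, self.CHROM_SIZES, 200_000)
        assert table.chains == [(0, 5), (5, 8)]


class TestContactsFromDistanceMap:
    def test_fully_missing(self):
        d = np.full((4, 4), np.nan)
        cmap, mask = contacts_from_distance_map(d, 1.0)
        assert cmap.n_contacts == 0
        assert mask.all()

    def test_single_entry_below_threshold(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = 0.5
        d[0, 1] = d[1, 0] = 5.0
        d[1, 2] = d[2, 1] = 5.0
        cmap, mask = contacts_from_distance_map(d, 1.0)
        assert cmap.pair_set() == {(0, 2)}
        assert not mask.any()

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        counts = [contacts_from_distance_map(d, t)[0].n_contacts
                  for t in (0.5, 1.0, 2.0, 4.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_missing_rows_masked(self):
        d = np.zeros((5, 5))
        d[:] = 3.0
        np.fill_diagonal(d, 0.0)
        d[2, :] = np.nan
        d[:, 2] = np.nan
        cmap, mask = contacts_from_distance_map(d, 1.0)
        assert mask[2].all() and mask[:, 2].all()
        assert not any(2 in p for p in cmap.pair_set())
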