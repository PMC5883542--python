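"""NJ trees, monophyly, MOTU sweeps and species delimitation vs. oracles."""

import itertools

import numpy as np
import pytest

from sycodiv.data_model import (
    CommunityDataset, Marker, MarkerAlignment, SequenceRecord,
)
from sycodiv.delimitation import (
    DEFAULT_CUTOFF_GRID, BarcodingGap, MOTUProfile, barcoding_gap,
    cross_continent_sisters, delimit_species, is_monophyletic, motu_sweep,
    nj_tree,
)
from sycodiv.distances import DistanceMatrix, distance_matrix
from sycodiv.synthetic_data import truth_check


def make_dm(ids, values, default=0.0):
    n = len(ids)
    d = np.full((n, n), default)
    np.fill_diagonal(d, 0.0)
    for (a, b), v in values.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(ids), d, np.full((n, n), 100))


def quartet_least_squares(ids, d):
    """Brute-force: fit branch lengths for all 3 quartet topologies, pick best.

    Returns (frozenset pair 1, frozenset pair 2) of the best-fitting topology.
    """
    best = None
    for (p, q), (r, s) in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        # branches: tips a,b,c,d = p,q,r,s and internal e
        rows, y = [], []
        pos = {p: 0, q: 1, r: 2, s: 3}
        for i, j in itertools.combinations(range(4), 2):
            row = [0.0] * 5
            row[pos[i]] = 1.0
            row[pos[j]] = 1.0
            same_side = {i, j} in ({p, q}, {r, s})
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            y.append(d[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = float(res[0]) if len(res) else 0.0
        if best is None or resid < best[0]:
            best = (resid, frozenset({ids[p], ids[q]}), frozenset({ids[r], ids[s]}))
    return best[1], best[2]


class TestNJTree:
    def test_recovers_additive_quartet(self):
        # true tree ((A:1,B:2):5,(C:3,D:4)) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = make_dm(ids, {
            ("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 9,
            ("A", "D"): 10, ("B", "C"): 10, ("B", "D"): 11,
        })
        tree = nj_tree(d)
        # oracle: exhaustive least squares over the 3 quartet topologies
        pair1, pair2 = quartet_least_squares(ids, d.d)
        assert {pair1, pair2} == {frozenset("AB"), frozenset("CD")}
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})
        # additive input: path lengths reproduced exactly
        paths = tree.node.tip_tip_distances()
        for a, b in itertools.combinations(ids, 2):
            assert paths[a, b] == pytest.approx(d.get(a, b), abs=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = make_dm(ids, {("A", "B"): 0.3, ("A", "C"): 0.5, ("B", "C"): 0.6})
        tree = nj_tree(d)
        paths = tree.node.tip_tip_distances()
        # three-point equations have an exact solution; NJ must reproduce it
        for a, b in itertools.combinations(ids, 2):
            assert paths[a, b] == pytest.approx(d.get(a, b), abs=1e-12)

    def test_ultrametric_tight_pairs_are_neighbors(self):
        ids = ["A", "B", "C", "D"]
        d = make_dm(ids, {("A", "B"): 0.1, ("C", "D"): 0.1}, default=1.0)
        tree = nj_tree(d)
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})

    def test_too_few_ids_raise(self):
        d = make_dm(["A", "B"], {("A", "B"): 0.1})
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_undefined_entries_raise_listing_pairs(self):
        d = make_dm(["A", "B", "C"], {("A", "B"): 0.1})
        d.d[0, 2] = d.d[2, 0] = np.nan
        d.undefined_pairs = [("A", "C")]
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(d)


class TestMonophyly:
    @pytest.fixture()
    def quartet(self):
        return nj_tree(make_dm(["A", "B", "C", "D"], {
            ("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 9,
            ("A", "D"): 10, ("B", "C"): 10, ("B", "D"): 11,
        }))

    def test_full_and_singleton_sets_trivially_true(self, quartet):
        assert is_monophyletic(quartet, {"A", "B", "C", "D"})
        assert is_monophyletic(quartet, {"C"})

    def test_exhaustive_bipartition_check(self, quartet):
        # ((A,B),(C,D)): valid non-trivial sides are {A,B} and {C,D} (and
        # complements); everything else is non-monophyletic
        for subset_size in (2, 3):
            for sub in itertools.combinations("ABCD", subset_size):
                expected = set(sub) in (
                    {"A", "B"}, {"C", "D"},
                    {"A", "C", "D"}, {"B", "C", "D"},
                    {"A", "B", "C"}, {"A", "B", "D"},
                )
                assert is_monophyletic(quartet, set(sub)) == expected

    def test_unknown_tip_raises(self, quartet):
        with pytest.raises(KeyError):
            is_monophyletic(quartet, {"A", "Z"})


class TestMotuSweep:
    def test_three_taxon_cutoffs(self):
        dm = make_dm(["A", "B", "C"],
                     {("A", "B"): 0.01, ("A", "C"): 0.05, ("B", "C"): 0.05})
        prof = motu_sweep(dm, np.array([0.0, 0.03, 0.05]))
        assert list(prof.counts) == [3, 2, 1]
        part = prof.partition_at(0.03)
        assert part["A"] == part["B"] != part["C"]

    def test_counts_match_networkx_components(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        n = 12
        d = np.round(rng.uniform(0, 0.1, size=(n, n)), 4)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d, np.full((n, n), 100))
        grid = np.round(np.arange(0.0, 0.105, 0.005), 6)
        prof = motu_sweep(dm, grid)
        for k, c in enumerate(grid):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if d[i, j] <= c:
                        g.add_edge(i, j)
            assert prof.counts[k] == nx.number_connected_components(g)

    def test_partitions_nested_and_counts_monotone(self):
        rng = np.random.default_rng(11)
        n = 10
        d = rng.uniform(0, 0.1, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d, np.full((n, n), 100))
        prof = motu_sweep(dm, np.round(np.arange(0.0, 0.1, 0.0025), 6))
        assert np.all(np.diff(prof.counts) <= 0)
        for a, b in zip(prof.partitions, prof.partitions[1:]):
            # coarsening: same label at the finer level implies same label later
            for i in range(n):
                for j in range(n):
                    if a[i] == a[j]:
                        assert b[i] == b[j]

    def test_ascending_grid_required(self):
        dm = make_dm(["A", "B"], {("A", "B"): 0.01})
        with pytest.raises(ValueError):
            motu_sweep(dm, np.array([0.05, 0.01]))


class TestBarcodingGap:
    def _profile(self, counts):
        counts = np.asarray(counts)
        cutoffs = np.arange(len(counts), dtype=float)
        return MOTUProfile(cutoffs, counts, [np.zeros(1)] * len(counts), ["x"])

    def test_longest_plateau_excluding_terminal_singleton(self):
        gap = barcoding_gap(self._profile([10, 6, 6, 6, 6, 2, 1, 1]))
        assert gap.motu_count == 6 and gap.span == 4
        assert (gap.cutoff_low, gap.cutoff_high) == (1.0, 4.0)

    def test_strictly_decreasing_counts_no_gap(self):
        assert barcoding_gap(self._profile([5, 4, 3, 2, 1])) is None

    def test_constant_profile_no_gap(self):
        assert barcoding_gap(self._profile([4, 4, 4, 4])) is None

    def test_tie_broken_toward_lower_cutoff(self):
        gap = barcoding_gap(self._profile([8, 8, 4, 4, 2, 1]))
        assert gap.motu_count == 8 and gap.cutoff_low == 0.0

    def test_two_species_fixture_plateau_at_two(self):
        # intra <= 1%, inter >= 6% -> plateau of 2 MOTUs across ~1-6%
        dm = make_dm(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.008, ("b1", "b2"): 0.01}, default=0.065,
        )
        gap = barcoding_gap(motu_sweep(dm, DEFAULT_CUTOFF_GRID))
        assert gap is not None and gap.motu_count == 2
        assert gap.cutoff_low <= 0.0125 and gap.cutoff_high >= 0.06


class TestDelimitSpecies:
    def test_recovers_synthetic_truth_with_separation(self, tight_community):
        _, dataset, truth = tight_community
        hyps = delimit_species(dataset)
        score = truth_check(hyps, truth)
        assert score.exact
        assert sum(1 for h in hyps if h.conflicts) == 0
        per_region = {"CN": 0, "AUS": 0}
        for h in hyps:
            per_region[h.region.value] += 1
        assert per_region == {"CN": 14, "AUS": 14}

    def test_order_and_relabel_invariance(self, tight_community):
        _, dataset, truth = tight_community
        coi = dataset.alignments[Marker.COI]
        shuffled = CommunityDataset(
            {Marker.COI: MarkerAlignment(Marker.COI, list(reversed(coi.records))),
             Marker.ITS2: dataset.alignments[Marker.ITS2]},
            list(reversed(dataset.metadata)),
        )
        a = {frozenset(h.members) for h in delimit_species(dataset)}
        b = {frozenset(h.members) for h in delimit_species(shuffled)}
        assert a == b

    def test_swapped_its2_flagged_as_conflict(self, tight_community):
        _, dataset, _ = tight_community
        its2 = dataset.alignments[Marker.ITS2]
        # give one Sycophila C1 individual the ITS2 of a C2 individual
        recs = {r.sample_id: r for r in its2.records}
        donor = recs["Sycophila_C2_01"].residues
        swapped = [
            SequenceRecord(r.sample_id, Marker.ITS2, donor)
            if r.sample_id == "Sycophila_C1_01" else r
            for r in its2.records
        ]
        ds2 = CommunityDataset(
            {Marker.COI: dataset.alignments[Marker.COI],
             Marker.ITS2: MarkerAlignment(Marker.ITS2, swapped)},
            dataset.metadata,
        )
        hyps = delimit_species(ds2)
        conflicted = {m for h in hyps for m in h.conflicts}
        assert "Sycophila_C1_01" in conflicted
        # assignment stays with COI
        sp = next(h for h in hyps if "Sycophila_C1_01" in h.members)
        assert "Sycophila_C1_02" in sp.members

    def test_its2_only_clade_flagged_possible_extra(self, tight_community):
        _, dataset, _ = tight_community
        coi = dataset.alignments[Marker.COI]
        # strip COI from an entire Philotrypesis species: its members form a
        # coherent nuclear-only clade
        victims = {f"Philotrypesis_A2_{i:02d}" for i in (1, 2, 3, 4)}
        kept = [r for r in coi.records if r.sample_id not in victims]
        ds2 = CommunityDataset(
            {Marker.COI: MarkerAlignment(Marker.COI, kept),
             Marker.ITS2: dataset.alignments[Marker.ITS2]},
            dataset.metadata,
        )
        hyps = delimit_species(ds2)
        extras = [h for h in hyps if h.possible_extra]
        assert len(extras) == 1
        assert set(extras[0].members) == victims

    def test_singleton_flagged_low_confidence(self, tight_community):
        _, dataset, _ = tight_community
        coi = dataset.alignments[Marker.COI]
        its2 = dataset.alignments[Marker.ITS2]
        keep = [i for i in coi.sample_ids if not i.startswith("Ormyrus")] + \
               ["Ormyrus_C1_01"]
        ds2 = CommunityDataset(
            {Marker.COI: coi.subset([i for i in coi.sample_ids if i in keep]),
             Marker.ITS2: its2.subset([i for i in its2.sample_ids if i in keep])},
            [r for r in dataset.metadata if r.sample_id in keep],
        )
        hyps = delimit_species(ds2)
        orm = [h for h in hyps if h.genus == "Ormyrus"]
        assert len(orm) == 1 and orm[0].low_confidence


class TestCrossContinentSisters:
    def test_single_species_per_side_is_sister_pair(self, tight_community):
        _, dataset, _ = tight_community
        hyps = delimit_species(dataset)
        eupr = [h for h in hyps if h.genus == "Eupristina"]
        reports = cross_continent_sisters(dataset, eupr)
        assert len(reports) == 1
        assert reports[0].inter_min > 0.05

    def test_local_congeners_closer_not_reported(self):
        # two CN species at 2% of each other, one AUS species 20% away:
        # the CN pair is mutually nearest, so no intercontinental sisters
        from sycodiv.data_model import Guild, Region, WaspRecord, build_dataset
        from sycodiv.codivergence import simulate_pair

        cn1, cn2 = simulate_pair(0.002, 0.002, 0.002, 0.02, 3, 3, 394, seed=5)
        aus = [s[::-1] for s in cn1[:3]]  # far from both CN species
        recs = []
        meta = []
        for tag, seqs in (("C1", cn1), ("C2", cn2), ("A1", aus)):
            region = Region.CN if tag.startswith("C") else Region.AUS
            for i, s in enumerate(seqs):
                sid = f"Walkerella_{tag}_{i:02d}"
                recs.append(SequenceRecord(sid, Marker.COI, s))
                meta.append(WaspRecord(sid, "Walkerella", region, Guild.SMALL_GALLER))
        ds = build_dataset([MarkerAlignment(Marker.COI, recs)], meta)
        hyps = delimit_species(ds)
        assert cross_continent_sisters(ds, hyps) == []

    def test_six_sister_genera_recovered_exactly(self, tight_community):
        _, dataset, truth = tight_community
        hyps = delimit_species(dataset)
        reports = cross_continent_sisters(dataset, hyps)
        assert sorted(r.genus for r in reports) == sorted(truth.pairs)
        for r in reports:
            assert r.inter_min <= r.inter_max
            if r.intra_cn:
                assert r.intra_cn[1] < r.inter_min
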