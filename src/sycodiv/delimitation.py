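"""Barcode species delimitation and intercontinental sister-pair detection.

Species are delimited per genus by the two-marker barcoding criteria:
single-linkage conspecificity on COI at a fixed 3% K2P cutoff (with the
empirical 95%-interval threshold reported alongside), checked for monophyly
on neighbor-joining trees built independently for each marker.  Individuals
whose two markers imply different groupings are assigned by COI and flagged
as conflicts; COI-less individuals forming a coherent nuclear-only clade are
flagged as possible additional species.  A MOTU cutoff sweep locates the
barcoding gap as the longest plateau in cluster counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .data_model import CommunityDataset, Marker, Region
from .distances import DistanceMatrix, distance_matrix, intraspecific_ci_threshold

__all__ = [
    "Tree",
    "MOTUProfile",
    "SpeciesHypothesis",
    "SisterPairReport",
    "nj_tree",
    "is_monophyletic",
    "motu_sweep",
    "barcoding_gap",
    "delimit_species",
    "cross_continent_sisters",
    "DEFAULT_CUTOFF_GRID",
]

#: Default MOTU sweep grid: 0–10% K2P in 0.25% steps.
DEFAULT_CUTOFF_GRID = np.round(np.arange(0.0, 0.10001, 0.0025), 6)


@dataclass
class Tree:
    """Unrooted tree over sample ids (thin wrapper around a skbio TreeNode)."""

    node: object  # skbio.TreeNode

    @property
    def tip_names(self) -> set[str]:
        return {t.name for t in self.node.tips()}

    def to_newick(self) -> str:
        return str(self.node)

    def bipartition_sides(self) -> list[frozenset[str]]:
        """Tip set below each internal edge of the (arbitrarily rooted) tree."""
        sides = []
        for n in self.node.non_tips(include_self=False):
            sides.append(frozenset(t.name for t in n.tips()))
        return sides


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree on a K2P matrix.

    Exact on additive matrices; negative branch-length estimates are clamped
    to zero.  Undefined (saturated) entries are an error naming the pairs.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 ids")
    if dm.undefined_pairs or np.isnan(dm.d).any():
        raise ValueError(
            f"distance matrix has undefined entries: {dm.undefined_pairs}"
        )
    import skbio
    from skbio.tree import nj as _nj

    sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.ids)
    return Tree(_nj(sk_dm, neg_as_zero=True))


def is_monophyletic(tree: Tree, tip_set: set[str]) -> bool:
    """True iff *tip_set* is one side of an edge bipartition of the unrooted tree.

    Singletons and the full tip set are trivially monophyletic.
    """
    tips = tree.tip_names
    tip_set = set(tip_set)
    if not tip_set:
        raise ValueError("tip_set must be non-empty")
    unknown = tip_set - tips
    if unknown:
        raise KeyError(f"unknown tip id(s): {sorted(unknown)}")
    # singletons, complements of singletons (terminal-edge bipartitions) and
    # the full set are monophyletic on any unrooted tree
    if len(tip_set) in (1, len(tips) - 1, len(tips)):
        return True
    target = frozenset(tip_set)
    complement = frozenset(tips - tip_set)
    for side in tree.bipartition_sides():
        if side == target or side == complement:
            return True
    # terminal edges define singleton|rest bipartitions, covered above
    return False


@dataclass
class MOTUProfile:
    """MOTU counts and partitions across an ascending cutoff grid."""

    cutoffs: np.ndarray
    counts: np.ndarray
    partitions: list[np.ndarray]  # per cutoff: cluster label per id
    ids: list[str]
    n_undefined: int = 0

    def partition_at(self, cutoff: float) -> dict[str, int]:
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        return dict(zip(self.ids, (int(x) for x in self.partitions[i])))


def motu_sweep(dm: DistanceMatrix, cutoff_grid=DEFAULT_CUTOFF_GRID) -> MOTUProfile:
    """Single-linkage MOTU clustering at each cutoff of an ascending grid.

    An edge joins two samples iff their distance is <= the cutoff; MOTUs are
    the connected components.  Undefined (saturated) distances contribute no
    edge and are counted as a warning.
    """
    cutoffs = np.asarray(cutoff_grid, dtype=float)
    if cutoffs.size and np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoff grid must be strictly ascending")
    n_und = int(np.isnan(dm.d[np.triu_indices(dm.n, 1)]).sum())
    if n_und:
        warnings.warn(f"{n_und} undefined distance(s) treated as no-edge")
    counts = np.empty(cutoffs.size, dtype=int)
    partitions = []
    with np.errstate(invalid="ignore"):
        for k, c in enumerate(cutoffs):
            adj = csr_matrix((dm.d <= c).astype(np.int8))
            n_comp, labels = connected_components(adj, directed=False)
            counts[k] = n_comp
            partitions.append(labels)
    return MOTUProfile(cutoffs, counts, partitions, list(dm.ids), n_und)


@dataclass(frozen=True)
class BarcodingGap:
    """Longest constant-count plateau of a MOTU sweep (the barcoding gap)."""

    cutoff_low: float
    cutoff_high: float
    motu_count: int
    span: int  # number of consecutive grid points

    @property
    def found(self) -> bool:
        return self.span >= 2


def barcoding_gap(profile: MOTUProfile) -> BarcodingGap | None:
    """Longest run of consecutive cutoffs with a constant MOTU count.

    The terminal plateau at one single cluster is excluded; ties break toward
    the lower cutoff.  Returns ``None`` (no-gap) when the counts are constant
    over the whole grid or strictly decreasing everywhere.
    """
    counts = profile.counts
    if counts.size < 3:
        raise ValueError("profile must cover at least 3 cutoffs")
    if np.all(counts == counts[0]):
        return None
    best = None  # (span, start, end)
    start = 0
    for i in range(1, counts.size + 1):
        if i == counts.size or counts[i] != counts[start]:
            run = i - start
            is_terminal_single = counts[start] == 1 and i == counts.size
            if not is_terminal_single:
                if best is None or run > best[0]:
                    best = (run, start, i - 1)
            start = i
    if best is None or best[0] < 2:
        return None
    span, lo, hi = best
    return BarcodingGap(
        float(profile.cutoffs[lo]), float(profile.cutoffs[hi]),
        int(counts[lo]), span,
    )


@dataclass
class SpeciesHypothesis:
    """One delimited species with per-criterion support flags."""

    species_id: str
    members: list[str]
    genus: str
    region: Region
    monophyly_coi: bool | None = None
    monophyly_its2: bool | None = None
    within_3pct: bool = False
    within_ci: bool | None = None
    conflicts: list[str] = field(default_factory=list)
    possible_extra: bool = False
    low_confidence: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)


def _single_linkage(dm: DistanceMatrix, threshold: float) -> list[list[str]]:
    with np.errstate(invalid="ignore"):
        adj = csr_matrix((dm.d <= threshold).astype(np.int8))
    _, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for sid, lab in zip(dm.ids, labels):
        clusters.setdefault(int(lab), []).append(sid)
    return [sorted(v) for v in sorted(clusters.values(), key=lambda c: sorted(c)[0])]


def delimit_species(
    dataset: CommunityDataset,
    coi_threshold: float = 0.03,
    its2_threshold: float = 0.03,
) -> list[SpeciesHypothesis]:
    """Delimit species per genus from COI clusters cross-checked by both markers.

    The primary partition is single-linkage on COI K2P at *coi_threshold*
    (the fixed 3% rule), split by region.  For every species the empirical
    95%-interval rule and per-marker monophyly on NJ trees are reported as
    flags; the fixed rule decides the partition when the two disagree.
    Individuals with incongruent ITS2 placement stay in their COI species and
    are listed as conflicts; COI-less ITS2 clusters unattached to any COI
    species become hypotheses flagged ``possible_extra``.
    """
    coi = dataset.alignments.get(Marker.COI)
    its2 = dataset.alignments.get(Marker.ITS2)
    if coi is None and its2 is None:
        raise ValueError("dataset has no marker alignments")
    hypotheses: list[SpeciesHypothesis] = []
    for genus in dataset.genera:
        genus_ids = [r.sample_id for r in dataset.metadata if r.genus == genus]
        hypotheses.extend(
            _delimit_genus(dataset, genus, genus_ids, coi, its2,
                           coi_threshold, its2_threshold)
        )
    # empirical-CI flag needs the pooled intraspecific distribution
    _apply_ci_flags(dataset, hypotheses)
    return hypotheses


def _delimit_genus(dataset, genus, genus_ids, coi, its2, coi_thr, its2_thr):
    coi_ids = [i for i in genus_ids if coi and i in coi.sample_ids]
    its2_ids = [i for i in genus_ids if its2 and i in its2.sample_ids]
    coi_dm = distance_matrix(coi.subset(coi_ids)) if len(coi_ids) >= 2 else None
    its2_dm = distance_matrix(its2.subset(its2_ids)) if len(its2_ids) >= 2 else None

    if coi_dm is not None:
        clusters = _single_linkage(coi_dm, coi_thr)
    elif coi_ids:
        clusters = [[i] for i in coi_ids]
    else:
        clusters = []
    # species cannot span regions: split clusters by region
    split: list[list[str]] = []
    for cl in clusters:
        by_region: dict[Region, list[str]] = {}
        for sid in cl:
            by_region.setdefault(dataset.record(sid).region, []).append(sid)
        split.extend(sorted(v) for v in by_region.values())
    clusters = split

    its2_clusters = (
        _single_linkage(its2_dm, its2_thr) if its2_dm is not None
        else ([[i] for i in its2_ids] if its2_ids else [])
    )
    its2_cluster_of = {sid: k for k, cl in enumerate(its2_clusters) for sid in cl}

    # attach COI-less individuals to the species their ITS2 cluster points at;
    # whole COI-less ITS2 clusters become possible extra species
    species_of: dict[str, int] = {
        sid: k for k, cl in enumerate(clusters) for sid in cl
    }
    extra_clusters: list[list[str]] = []
    unplaced = [i for i in genus_ids if i not in species_of]
    handled: set[str] = set()
    for sid in unplaced:
        if sid in handled:
            continue
        k = its2_cluster_of.get(sid)
        if k is None:
            extra_clusters.append([sid])  # no data on either marker cluster
            handled.add(sid)
            continue
        mates = its2_clusters[k]
        anchored = {species_of[m] for m in mates if m in species_of}
        cluster_unplaced = [m for m in mates if m not in species_of]
        if len(anchored) == 1:
            target = anchored.pop()
            for m in cluster_unplaced:
                clusters[target].append(m)
                species_of[m] = target
                handled.add(m)
        else:
            extra_clusters.append(sorted(cluster_unplaced))
            handled.update(cluster_unplaced)

    trees = {}
    for marker, dmx in (("COI", coi_dm), ("ITS2", its2_dm)):
        if dmx is not None and dmx.n >= 3 and not dmx.undefined_pairs:
            trees[marker] = nj_tree(dmx)

    out: list[SpeciesHypothesis] = []
    n_by_region: dict[Region, int] = {}
    all_clusters = [(cl, False) for cl in clusters] + [(cl, True) for cl in extra_clusters]
    for members, is_extra in all_clusters:
        members = sorted(members)
        region = dataset.record(members[0]).region
        n_by_region[region] = n_by_region.get(region, 0) + 1
        prefix = "C" if region == Region.CN else "A"
        sp = SpeciesHypothesis(
            species_id=f"{genus}_{prefix}{n_by_region[region]}",
            members=members,
            genus=genus,
            region=region,
            possible_extra=is_extra,
            low_confidence=len(members) == 1,
        )
        coi_members = [m for m in members if coi and m in coi.sample_ids]
        its2_members = [m for m in members if its2 and m in its2.sample_ids]
        # 3% rule: every COI member has a conspecific within threshold
        if coi_dm is not None and len(coi_members) >= 2:
            sub = coi_dm.submatrix(coi_members)
            offdiag = sub.d + np.where(np.eye(sub.n, dtype=bool), np.inf, 0.0)
            with np.errstate(invalid="ignore"):
                sp.within_3pct = bool(np.all(np.nanmin(offdiag, axis=1) <= coi_thr))
        for marker, tree in trees.items():
            mm = coi_members if marker == "COI" else its2_members
            flag = is_monophyletic(tree, set(mm)) if len(mm) >= 2 else None
            if marker == "COI":
                sp.monophyly_coi = flag
            else:
                sp.monophyly_its2 = flag
        # marker incongruence: an individual whose ITS2 cluster-mates belong
        # to a different COI species is flagged (assignment stays with COI)
        for m in members:
            k = its2_cluster_of.get(m)
            if k is None:
                continue
            mates = [x for x in its2_clusters[k] if x != m and x in species_of]
            if mates and all(species_of[x] != species_of.get(m, -1) for x in mates):
                if m in species_of:
                    sp.conflicts.append(m)
        out.append(sp)
    return out


def _apply_ci_flags(dataset, hypotheses):
    coi = dataset.alignments.get(Marker.COI)
    if coi is None:
        return
    # pooled intraspecific COI distances across the primary partition
    intra: list[float] = []
    per_species: dict[str, np.ndarray] = {}
    for sp in hypotheses:
        members = [m for m in sp.members if m in coi.sample_ids]
        if len(members) < 2:
            continue
        dmx = distance_matrix(coi.subset(members))
        vals = dmx.d[np.triu_indices(dmx.n, 1)]
        vals = vals[~np.isnan(vals)]
        intra.extend(float(v) for v in vals)
        per_species[sp.species_id] = dmx.d
    if len(intra) < 2:
        return
    thr = intraspecific_ci_threshold(intra)
    for sp in hypotheses:
        d = per_species.get(sp.species_id)
        if d is None:
            continue
        offdiag = d + np.where(np.eye(d.shape[0], dtype=bool), np.inf, 0.0)
        with np.errstate(invalid="ignore"):
            sp.within_ci = bool(np.all(np.nanmin(offdiag, axis=1) <= thr))


@dataclass(frozen=True)
class SisterPairReport:
    """A mutual-nearest intercontinental species pair with K2P ranges."""

    genus: str
    species_cn: str
    species_aus: str
    inter_min: float
    inter_max: float
    intra_cn: tuple[float, float] | None
    intra_aus: tuple[float, float] | None


def cross_continent_sisters(
    dataset: CommunityDataset, hypotheses: list[SpeciesHypothesis]
) -> list[SisterPairReport]:
    """Mutual-nearest-neighbour species pairs spanning the two regions.

    For every species the nearest heterospecific congener is found by
    minimum pairwise COI K2P between members; a pair is reported iff each
    member's nearest heterospecific is the other and the two species come
    from different regions.  A genus present in one region only contributes
    nothing.
    """
    coi = dataset.alignments.get(Marker.COI)
    if coi is None:
        raise ValueError("cross-continent sister detection requires COI")
    reports: list[SisterPairReport] = []
    by_genus: dict[str, list[SpeciesHypothesis]] = {}
    for sp in hypotheses:
        by_genus.setdefault(sp.genus, []).append(sp)
    for genus in sorted(by_genus):
        sps = [
            sp for sp in by_genus[genus]
            if any(m in coi.sample_ids for m in sp.members)
        ]
        regions = {sp.region for sp in sps}
        if len(sps) < 2 or len(regions) < 2:
            continue
        genus_ids = [m for sp in sps for m in sp.members if m in coi.sample_ids]
        dm = distance_matrix(coi.subset(genus_ids))
        idx_of = {sid: k for k, sid in enumerate(dm.ids)}

        def block(a: SpeciesHypothesis, b: SpeciesHypothesis) -> np.ndarray:
            ia = [idx_of[m] for m in a.members if m in idx_of]
            ib = [idx_of[m] for m in b.members if m in idx_of]
            return dm.d[np.ix_(ia, ib)]

        nearest: dict[str, tuple[str, float]] = {}
        for a in sps:
            best = None
            for b in sps:
                if b.species_id == a.species_id:
                    continue
                blk = block(a, b)
                if np.all(np.isnan(blk)):
                    continue
                v = float(np.nanmin(blk))
                if best is None or v < best[1]:
                    best = (b.species_id, v)
            if best:
                nearest[a.species_id] = best
        sp_by_id = {sp.species_id: sp for sp in sps}
        seen: set[frozenset[str]] = set()
        for a in sps:
            na = nearest.get(a.species_id)
            if na is None:
                continue
            b = sp_by_id[na[0]]
            nb = nearest.get(b.species_id)
            if nb is None or nb[0] != a.species_id:
                continue
            if a.region == b.region:
                continue
            key = frozenset({a.species_id, b.species_id})
            if key in seen:
                continue
            seen.add(key)
            cn, aus = (a, b) if a.region == Region.CN else (b, a)
            blk = block(cn, aus)

            def intra_range(sp: SpeciesHypothesis) -> tuple[float, float] | None:
                ids = [m for m in sp.members if m in idx_of]
                if len(ids) < 2:
                    return None
                ii = [idx_of[m] for m in ids]
                vals = dm.d[np.ix_(ii, ii)][np.triu_indices(len(ii), 1)]
                vals = vals[~np.isnan(vals)]
                return (float(vals.min()), float(vals.max())) if vals.size else None

            reports.append(
                SisterPairReport(
                    genus, cn.species_id, aus.species_id,
                    float(np.nanmin(blk)), float(np.nanmax(blk)),
                    intra_range(cn), intra_range(aus),
                )
            )
    return reports
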