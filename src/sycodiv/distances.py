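"""Kimura 2-parameter distances and intra/inter-group distance summaries.

The K2P distance corrects separately for transitions (proportion P) and
transversions (proportion Q) among pairwise-complete columns:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Gap and N columns are handled by pairwise deletion: a column contributes to a
pair only when both sequences carry an unambiguous base there.  When the
logarithm's argument is non-positive the pair is saturated and its entry is
flagged undefined (NaN) rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import MarkerAlignment

__all__ = [
    "DistanceMatrix",
    "DistanceSummary",
    "UndefinedDistanceError",
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "summarize_groups",
    "intraspecific_ci_threshold",
    "encode_alignment",
]

# encoding: A=0, G=1, C=2, T=3 (purines < 2 <= pyrimidines), invalid=4
_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"AGCT", (0, 1, 2, 3)):
    _CODE[_b] = _c


class UndefinedDistanceError(ValueError):
    """No pairwise-complete column exists for a sequence pair."""


def encode_alignment(seqs: list[str]) -> np.ndarray:
    """Encode sequences to a (n, L) uint8 matrix (A=0,G=1,C=2,T=3, other=4)."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        return 0.0, 0.0, 0
    av, bv = a[valid], b[valid]
    diff = av != bv
    # transition: both purines or both pyrimidines (same // 2 class)
    ts = int((diff & ((av >> 1) == (bv >> 1))).sum())
    tv = int(diff.sum()) - ts
    return ts / n, tv / n, n


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance (substitutions/site) and count of pairwise-complete columns.

    Returns ``(nan, valid_sites)`` when the pair is saturated (log argument
    non-positive).  Raises :class:`UndefinedDistanceError` when no column is
    pairwise complete, and ``ValueError`` on unequal lengths.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}")
    a, b = encode_alignment([seq_a, seq_b])
    p, q, n = _pq(a, b)
    if n == 0:
        raise UndefinedDistanceError("no pairwise-complete columns")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, n
    return -0.5 * math.log(w1 * math.sqrt(w2)), n


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected proportion of differing pairwise-complete sites (diagnostic)."""
    a, b = encode_alignment([seq_a, seq_b])
    p, q, n = _pq(a, b)
    if n == 0:
        raise UndefinedDistanceError("no pairwise-complete columns")
    return p + q, n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P matrix with per-pair valid-site counts.

    Saturated entries are NaN; ``undefined_pairs`` lists them explicitly.
    """

    ids: list[str]
    d: np.ndarray
    valid_sites: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.valid_sites.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        sub = self.d[np.ix_(idx, idx)]
        vs = self.valid_sites[np.ix_(idx, idx)]
        keep = set(ids)
        und = [(a, b) for a, b in self.undefined_pairs if a in keep and b in keep]
        return DistanceMatrix(list(ids), sub, vs, und)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{name:<10s} {row}\n")


def distance_matrix(aln: MarkerAlignment) -> DistanceMatrix:
    """All-pairs K2P matrix for an alignment (pairwise deletion, saturation as NaN)."""
    if len(aln) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    enc = encode_alignment([r.residues for r in aln.records])
    n = len(aln)
    d = np.zeros((n, n))
    vs = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(vs, aln.length)
    undefined: list[tuple[str, str]] = []
    valid = enc < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            vs[i, j] = vs[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = math.nan
                undefined.append((aln.sample_ids[i], aln.sample_ids[j]))
                continue
            ai, aj = enc[i][both], enc[j][both]
            diff = ai != aj
            ts = int((diff & ((ai >> 1) == (aj >> 1))).sum())
            tv = int(diff.sum()) - ts
            p, q = ts / m, tv / m
            w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
            if w1 <= 0.0 or w2 <= 0.0:
                d[i, j] = d[j, i] = math.nan
                undefined.append((aln.sample_ids[i], aln.sample_ids[j]))
            else:
                d[i, j] = d[j, i] = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistanceMatrix(list(aln.sample_ids), d, vs, undefined)


@dataclass
class DistanceSummary:
    """Intra-group distance summary plus nearest heterospecific neighbour."""

    group: str
    n_members: int
    max_intra: float | None
    intra_q025: float | None
    intra_q975: float | None
    nearest_group: str | None
    nearest_min: float | None
    nearest_max: float | None
    n_undefined_excluded: int = 0

    @property
    def applicable(self) -> bool:
        """False for singleton groups (no intra pair exists)."""
        return self.max_intra is not None


def summarize_groups(
    dm: DistanceMatrix, grouping: dict[str, str]
) -> list[DistanceSummary]:
    """Per-group intra-distance summaries and nearest other-group neighbours.

    *grouping* maps every id in *dm* to exactly one group label.  Undefined
    (saturated) entries are excluded and counted, never imputed.  Singleton
    groups yield a summary with ``max_intra=None`` (not an exception).
    """
    missing = [i for i in dm.ids if i not in grouping]
    if missing:
        raise ValueError(f"ids without a group: {sorted(missing)}")
    groups = sorted(set(grouping.values()))
    by_group = {g: [i for i, x in enumerate(dm.ids) if grouping[x] == g] for g in groups}
    out = []
    for g in groups:
        idx = by_group[g]
        n_und = 0
        intra = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                v = dm.d[idx[a], idx[b]]
                if math.isnan(v):
                    n_und += 1
                else:
                    intra.append(v)
        if intra:
            arr = np.asarray(intra)
            mx = float(arr.max())
            q025, q975 = (float(x) for x in np.percentile(arr, [2.5, 97.5]))
        else:
            mx = q025 = q975 = None
        # nearest member of any other group
        other = [i for gg in groups if gg != g for i in by_group[gg]]
        nearest_group = nearest_min = nearest_max = None
        if other and idx:
            block = dm.d[np.ix_(idx, other)]
            n_und += int(np.isnan(block).sum())
            if not np.all(np.isnan(block)):
                j = int(np.nanargmin(block) % block.shape[1])
                nearest_id = dm.ids[other[j]]
                nearest_group = grouping[nearest_id]
                # min/max of defined distances to that nearest group
                gidx = by_group[nearest_group]
                gblock = dm.d[np.ix_(idx, gidx)]
                nearest_min = float(np.nanmin(gblock))
                nearest_max = float(np.nanmax(gblock))
        out.append(
            DistanceSummary(
                g, len(idx), mx, q025, q975,
                nearest_group, nearest_min, nearest_max, n_und,
            )
        )
    return out


def intraspecific_ci_threshold(intra_distances: np.ndarray | list[float]) -> float:
    """Upper bound of the 95% interval of pooled intraspecific distances.

    Implemented as the empirical 97.5th percentile; used as an alternative
    conspecificity threshold alongside the fixed 3% rule.
    """
    arr = np.asarray(intra_distances, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 intraspecific distances")
    return float(np.percentile(arr, 97.5))
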