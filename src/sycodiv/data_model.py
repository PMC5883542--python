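"""Core data containers for a two-marker fig-wasp community dataset.

A community dataset joins per-marker aligned sequences (COI standardised to a
fixed fragment length; ITS2 variable by genus) with per-sample metadata
(genus, region, ecological guild).  Every downstream stage — distances,
delimitation, co-divergence testing, dating, community comparison — consumes
the :class:`CommunityDataset` built here.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Marker",
    "Region",
    "Guild",
    "SequenceRecord",
    "MarkerAlignment",
    "WaspRecord",
    "CommunityDataset",
    "AlignmentError",
    "ValidationError",
    "JoinError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_metadata",
    "build_dataset",
    "DEFAULT_REGION_ALIASES",
]


class Marker(str, enum.Enum):
    """Sequenced marker: mitochondrial COI or nuclear ITS2."""

    COI = "COI"
    ITS2 = "ITS2"


class Region(str, enum.Enum):
    """Sampling region: Hainan, China (CN) or Queensland, Australia (AUS)."""

    CN = "CN"
    AUS = "AUS"


class Guild(str, enum.Enum):
    """Ecological guild of a fig-wasp genus.

    Five functional groups: pollinators, small (non-pollinating) gallers,
    small parasitoids/kleptoparasites, large gallers, large parasitoids.
    """

    POLLINATOR = "pollinator"
    SMALL_GALLER = "small_galler"
    SMALL_PARASITOID = "small_parasitoid"
    LARGE_GALLER = "large_galler"
    LARGE_PARASITOID = "large_parasitoid"


#: Free-text region aliases accepted by :func:`read_metadata`.
DEFAULT_REGION_ALIASES: Mapping[str, str] = {
    "CN": "CN",
    "CHINA": "CN",
    "HAINAN": "CN",
    "AUS": "AUS",
    "AU": "AUS",
    "AUSTRALIA": "AUS",
    "QUEENSLAND": "AUS",
}

_ALPHABET = set("ACGTN-")


class AlignmentError(ValueError):
    """Raised when sequences cannot form a valid alignment."""


class ValidationError(ValueError):
    """Raised when an input record violates a container invariant."""


class JoinError(ValueError):
    """Raised when sequence ids cannot be joined to metadata."""


def _normalize_residues(residues: str, sample_id: str) -> str:
    s = residues.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValidationError(
            f"sequence {sample_id!r}: unsupported residue(s) {sorted(bad)}; "
            "only A, C, G, T, N and '-' are accepted (ambiguity codes other "
            "than N must be resolved upstream)"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence for one sample and one marker."""

    sample_id: str
    marker: Marker
    residues: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.sample_id!r} is empty")
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, self.sample_id)
        )
        object.__setattr__(self, "marker", Marker(self.marker))


@dataclass
class MarkerAlignment:
    """An ordered, equal-length collection of sequences for one marker."""

    marker: Marker
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        self.marker = Marker(self.marker)
        if not self.records:
            raise AlignmentError(f"empty alignment for marker {self.marker.value}")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment for marker {self.marker.value}: "
                f"lengths {sorted(lengths)}"
            )
        ids = [r.sample_id for r in self.records]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise ValidationError(f"duplicate sample ids: {sorted(dups)}")
        for r in self.records:
            if r.marker != self.marker:
                raise ValidationError(
                    f"record {r.sample_id!r} is {r.marker.value}, "
                    f"alignment is {self.marker.value}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "MarkerAlignment":
        """Alignment restricted to *ids*, preserving input order."""
        keep = set(ids)
        missing = keep - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)}")
        return MarkerAlignment(
            self.marker, [r for r in self.records if r.sample_id in keep]
        )


@dataclass(frozen=True)
class WaspRecord:
    """Per-sample metadata row."""

    sample_id: str
    genus: str
    region: Region
    guild: Guild
    species_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.genus:
            raise ValidationError(f"sample {self.sample_id!r}: genus must be non-empty")
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "guild", Guild(self.guild))


@dataclass
class CommunityDataset:
    """Joined alignments and metadata for one two-region community."""

    alignments: dict[Marker, MarkerAlignment]
    metadata: list[WaspRecord]
    _by_id: dict[str, WaspRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.metadata:
            if rec.sample_id in self._by_id:
                raise ValidationError(f"duplicate metadata sample_id {rec.sample_id!r}")
            self._by_id[rec.sample_id] = rec
        # guild must be consistent per genus
        genus_guild: dict[str, Guild] = {}
        for rec in self.metadata:
            prev = genus_guild.setdefault(rec.genus, rec.guild)
            if prev != rec.guild:
                raise ValidationError(
                    f"genus {rec.genus!r} mapped to two guilds: "
                    f"{prev.value}, {rec.guild.value}"
                )
        for marker, aln in self.alignments.items():
            orphans = [i for i in aln.sample_ids if i not in self._by_id]
            if orphans:
                raise JoinError(
                    f"{marker.value} sequences without metadata: {sorted(orphans)}"
                )

    def record(self, sample_id: str) -> WaspRecord:
        return self._by_id[sample_id]

    @property
    def genera(self) -> list[str]:
        return sorted({r.genus for r in self.metadata})

    def guild_of(self, genus: str) -> Guild:
        for r in self.metadata:
            if r.genus == genus:
                return r.guild
        raise KeyError(genus)

    def samples_with(self, marker: Marker) -> list[str]:
        aln = self.alignments.get(Marker(marker))
        return aln.sample_ids if aln else []

    def missing_marker(self, marker: Marker) -> list[str]:
        """Metadata samples lacking a sequence for *marker*."""
        have = set(self.samples_with(marker))
        return [r.sample_id for r in self.metadata if r.sample_id not in have]

    def summary(self) -> dict:
        out: dict = {
            "n_samples": len(self.metadata),
            "n_genera": len(self.genera),
            "per_marker": {},
            "missing": {},
        }
        for marker in self.alignments:
            out["per_marker"][marker.value] = {
                "n_sequences": len(self.alignments[marker]),
                "length": self.alignments[marker].length,
            }
            out["missing"][marker.value] = self.missing_marker(marker)
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def read_fasta_alignment(path: str | Path, marker: Marker | str) -> MarkerAlignment:
    """Read an aligned FASTA file into a :class:`MarkerAlignment`.

    Input order is preserved.  Ragged record lengths raise
    :class:`AlignmentError`; duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    marker = Marker(marker)
    records = [
        SequenceRecord(rec.id, marker, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return MarkerAlignment(marker, records)


def write_fasta_alignment(aln: MarkerAlignment, path: str | Path) -> None:
    """Write an alignment back to FASTA (inverse of :func:`read_fasta_alignment`)."""
    recs = [
        _BioSeqRecord(Seq(r.residues), id=r.sample_id, description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


_REQUIRED_COLUMNS = ("sample_id", "genus", "region", "guild")


def read_metadata(
    path: str | Path,
    region_aliases: Mapping[str, str] = DEFAULT_REGION_ALIASES,
) -> list[WaspRecord]:
    """Read the sample metadata TSV.

    Required columns: sample_id, genus, region, guild; optional
    species_label.  Region strings are looked up case-insensitively in
    *region_aliases* before enum validation, so free-text inputs like
    "China" are accepted.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    records: list[WaspRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        sid = row.sample_id
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r} in metadata")
        seen.add(sid)
        raw_region = str(row.region).strip()
        region = region_aliases.get(raw_region.upper(), raw_region)
        try:
            region_enum = Region(region)
        except ValueError:
            raise ValidationError(
                f"sample {sid!r}: unknown region {raw_region!r} "
                f"(accepted: {sorted(set(region_aliases))})"
            ) from None
        try:
            guild_enum = Guild(str(row.guild).strip())
        except ValueError:
            raise ValidationError(
                f"sample {sid!r}: unknown guild {row.guild!r} "
                f"(accepted: {[g.value for g in Guild]})"
            ) from None
        label = getattr(row, "species_label", "") or None
        records.append(WaspRecord(sid, str(row.genus).strip(), region_enum, guild_enum, label))
    return records


def build_dataset(
    alignments: Mapping[Marker | str, MarkerAlignment] | Sequence[MarkerAlignment],
    metadata: Iterable[WaspRecord],
) -> CommunityDataset:
    """Join validated alignments and metadata into a :class:`CommunityDataset`.

    A sequence id absent from the metadata is a :class:`JoinError` naming the
    id.  A sample present for only one marker is legal; the dataset's
    :meth:`~CommunityDataset.summary` reports which samples miss which marker.
    """
    if isinstance(alignments, Mapping):
        aln_map = {Marker(k): v for k, v in alignments.items()}
    else:
        aln_map = {a.marker: a for a in alignments}
    return CommunityDataset(aln_map, list(metadata))
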