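"""Genus x region x guild community-composition tables and comparisons.

Builds the per-region species-richness table (counts per genus with maximum
intrageneric K2P where available) and quantifies intercontinental overlap:
shared vs. region-exclusive genera, shared species (expected zero when no
delimited species spans both regions) and per-guild richness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .data_model import Guild, Region, WaspRecord
from .delimitation import SpeciesHypothesis

__all__ = ["CommunityTable", "CompositionComparison", "community_table",
           "compare_communities"]

_REGIONS = [Region.CN, Region.AUS]


@dataclass
class CommunityTable:
    """Rows of (genus, guild, region, n_species, n_possible_extra, max intra K2P %)."""

    df: pd.DataFrame

    @classmethod
    def from_counts(cls, rows: list[tuple]) -> "CommunityTable":
        """Build directly from (genus, guild, region, n_species[, max_intra_pct]) rows."""
        recs = []
        for row in rows:
            genus, guild, region, n = row[:4]
            pct = row[4] if len(row) > 4 else None
            recs.append(
                dict(genus=genus, guild=Guild(guild).value,
                     region=Region(region).value, n_species=int(n),
                     n_possible_extra=0, max_intra_k2p_pct=pct)
            )
        return cls(pd.DataFrame(recs))

    def n_species(self, genus: str, region: Region | str) -> int:
        sel = self.df[(self.df.genus == genus) & (self.df.region == Region(region).value)]
        return int(sel.n_species.sum())

    def richness(self, region: Region | str, include_possible: bool = False) -> int:
        sel = self.df[self.df.region == Region(region).value]
        n = int(sel.n_species.sum())
        return n + int(sel.n_possible_extra.sum()) if include_possible else n

    def genera_in(self, region: Region | str) -> set[str]:
        sel = self.df[(self.df.region == Region(region).value) & (self.df.n_species > 0)]
        return set(sel.genus)

    def guild_of(self, genus: str) -> Guild:
        return Guild(self.df[self.df.genus == genus].guild.iloc[0])

    def totals(self) -> dict[str, int]:
        return {r.value: self.richness(r) for r in _REGIONS}

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_markdown(self) -> str:
        lines = ["| Genus | Guild | Region | Species | Possible extra | Max intra K2P (%) |",
                 "|---|---|---|---|---|---|"]
        for r in self.df.itertuples(index=False):
            pct = "" if r.max_intra_k2p_pct is None or pd.isna(r.max_intra_k2p_pct) \
                else f"{r.max_intra_k2p_pct:.1f}"
            lines.append(
                f"| {r.genus} | {r.guild} | {r.region} | {r.n_species} "
                f"| {r.n_possible_extra} | {pct} |"
            )
        tot = self.totals()
        lines.append(f"| **Total** | | CN {tot['CN']} / AUS {tot['AUS']} | | | |")
        return "\n".join(lines)


def community_table(
    hypotheses: list[SpeciesHypothesis],
    metadata: list[WaspRecord],
    max_intra_pct: dict[str, float] | None = None,
) -> CommunityTable:
    """Species counts per genus per region from delimited species.

    Guilds come from the metadata's genus->guild map; a genus present in the
    hypotheses but absent from the metadata raises.  Species flagged
    ``possible_extra`` are counted separately, never merged into the primary
    count.  *max_intra_pct* optionally supplies per-(genus, region) maximum
    intrageneric K2P in percent (keys ``"genus/REGION"``).
    """
    guild_map: dict[str, Guild] = {}
    for rec in metadata:
        guild_map.setdefault(rec.genus, rec.guild)
    missing = sorted({h.genus for h in hypotheses} - set(guild_map))
    if missing:
        raise ValueError(f"genera lacking a guild mapping: {missing}")
    recs = []
    genera = sorted(guild_map)
    for genus in genera:
        for region in _REGIONS:
            sps = [h for h in hypotheses if h.genus == genus and h.region == region]
            n_main = sum(1 for h in sps if not h.possible_extra)
            n_extra = sum(1 for h in sps if h.possible_extra)
            key = f"{genus}/{region.value}"
            recs.append(
                dict(genus=genus, guild=guild_map[genus].value, region=region.value,
                     n_species=n_main, n_possible_extra=n_extra,
                     max_intra_k2p_pct=(max_intra_pct or {}).get(key))
            )
    return CommunityTable(pd.DataFrame(recs))


@dataclass
class CompositionComparison:
    """Intercontinental community overlap summary."""

    shared_genera: list[str]
    exclusive_genera: dict[str, list[str]]
    shared_species: int
    shared_species_ids: list[str]
    richness: dict[str, int]
    richness_with_possible: dict[str, int]
    per_guild: dict[str, dict[str, int]]  # region -> guild -> n_species
    guilds_in_both: list[str] = field(default_factory=list)

    @property
    def n_shared_genera(self) -> int:
        return len(self.shared_genera)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def compare_communities(
    table: CommunityTable,
    hypotheses: list[SpeciesHypothesis] | None = None,
) -> CompositionComparison:
    """Shared/exclusive genera, shared species and per-guild richness.

    Shared species are counted by identical species_id across regions when
    hypotheses are supplied (a delimited species whose members span both
    regions); with region-consistent delimitation this is zero.  Raises on a
    single-region table.
    """
    present_regions = {r for r in _REGIONS if not table.df[table.df.region == r.value].empty}
    if len(present_regions) < 2:
        raise ValueError("comparison requires a table covering both regions")
    g_cn = table.genera_in(Region.CN)
    g_aus = table.genera_in(Region.AUS)
    shared = sorted(g_cn & g_aus)
    exclusive = {
        Region.CN.value: sorted(g_cn - g_aus),
        Region.AUS.value: sorted(g_aus - g_cn),
    }
    shared_sp_ids: list[str] = []
    if hypotheses is not None:
        by_id: dict[str, set[Region]] = {}
        for h in hypotheses:
            by_id.setdefault(h.species_id, set()).add(h.region)
        shared_sp_ids = sorted(i for i, rs in by_id.items() if len(rs) > 1)
    per_guild: dict[str, dict[str, int]] = {}
    for region in _REGIONS:
        sel = table.df[table.df.region == region.value]
        counts = sel.groupby("guild").n_species.sum()
        per_guild[region.value] = {g: int(n) for g, n in counts.items() if n > 0}
    guilds_both = sorted(
        set(per_guild[Region.CN.value]) & set(per_guild[Region.AUS.value])
    )
    return CompositionComparison(
        shared_genera=shared,
        exclusive_genera=exclusive,
        shared_species=len(shared_sp_ids),
        shared_species_ids=shared_sp_ids,
        richness=table.totals(),
        richness_with_possible={
            r.value: table.richness(r, include_possible=True) for r in _REGIONS
        },
        per_guild=per_guild,
        guilds_in_both=guilds_both,
    )
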