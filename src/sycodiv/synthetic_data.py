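"""Synthetic two-region fig-wasp communities with known truth.

Generates complete COI + ITS2 datasets mirroring the structure of the real
study system: nine genera across five guilds, fourteen species per region,
one intercontinental sister pair per shared genus (two-population isolation
coalescent at a configurable divergence time under a 1.9%-pairwise/Myr
clock), region-exclusive extra species, and a configurable fraction of
samples missing one marker.  Every emitted sequence carries a truth record
(species, genus, region, guild; per-pair divergence times and thetas) so
that delimitation, co-divergence and dating stages can be scored exactly.

Within a genus, each non-sister species joins the genus backbone at a
strictly deeper, regularly staggered time (base + k*step Myr).  Distinct
join times make nearest-neighbour relations deterministic: the sister pair
is always mutually nearest, and no extra species can form a spurious
cross-continental mutual pair.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels
from .codivergence import SisterPairDataset
from .data_model import (
    CommunityDataset, Guild, Marker, MarkerAlignment, Region, SequenceRecord,
    WaspRecord, build_dataset, write_fasta_alignment,
)
from .delimitation import SpeciesHypothesis

__all__ = [
    "GenusConfig",
    "CommunityConfig",
    "TruthRecord",
    "Scorecard",
    "simulate_community",
    "truth_check",
    "sister_pairs_from_truth",
]

_DECODE = np.frombuffer(b"AGCT", dtype=np.uint8)


@dataclass(frozen=True)
class GenusConfig:
    name: str
    guild: Guild
    n_species_cn: int
    n_species_aus: int
    cross_sisters: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "guild", Guild(self.guild))
        if self.cross_sisters and (self.n_species_cn < 1 or self.n_species_aus < 1):
            raise ValueError(
                f"genus {self.name!r}: cross_sisters requires >=1 species per region"
            )


@dataclass
class CommunityConfig:
    """Generator settings; the defaults mirror the real study's conditions.

    ``tau_ma`` sets sister-pair divergence times (Myr): a single shared
    value, a guild->value mapping, or a per-genus mapping.  Non-sister
    species join at ``congener_base_ma + k * congener_step_ma``.
    """

    genera: list[GenusConfig]
    n_individuals: int = 4
    L_coi: int = 394
    L_its2: int = 400
    theta: float = 0.005
    tau_ma: float | dict = 5.2
    congener_base_ma: float = 10.0
    congener_step_ma: float = 3.0
    clock_rate: float = 0.019
    its2_rate_multiplier: float = 0.3
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")
        if self.theta <= 0 or self.clock_rate <= 0:
            raise ValueError("theta and clock_rate must be > 0")
        for g in self.genera:
            if g.cross_sisters and self.tau_for(g) >= self.congener_base_ma:
                raise ValueError(
                    f"sister divergence for {g.name!r} ({self.tau_for(g)} Ma) must "
                    f"be shallower than congener_base_ma ({self.congener_base_ma})"
                )

    def tau_for(self, genus: GenusConfig) -> float:
        if isinstance(self.tau_ma, dict):
            key = genus.name if genus.name in self.tau_ma else genus.guild.value
            return float(self.tau_ma[key])
        return float(self.tau_ma)

    @classmethod
    def study_system(cls, seed: int = 0, **overrides) -> "CommunityConfig":
        """Nine genera, five guilds, 14 + 14 species, six sister-pair genera."""
        genera = [
            GenusConfig("Eupristina", Guild.POLLINATOR, 1, 1, True),
            GenusConfig("Philotrypesis", Guild.SMALL_PARASITOID, 4, 3, True),
            GenusConfig("Sycoscapter", Guild.SMALL_PARASITOID, 2, 3, True),
            GenusConfig("Sycorycteridea", Guild.SMALL_PARASITOID, 0, 1, False),
            GenusConfig("Walkerella", Guild.SMALL_GALLER, 2, 2, True),
            GenusConfig("Sycobia", Guild.LARGE_GALLER, 1, 1, True),
            GenusConfig("Sycophila", Guild.LARGE_PARASITOID, 2, 3, True),
            GenusConfig("Acophila", Guild.LARGE_GALLER, 1, 0, False),
            GenusConfig("Ormyrus", Guild.LARGE_PARASITOID, 1, 0, False),
        ]
        overrides.setdefault("missing_fraction", 0.1)
        return cls(genera=genera, seed=seed, **overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        for g in d["genera"]:
            g["guild"] = Guild(g["guild"]).value
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityConfig":
        d = dict(d)
        d["genera"] = [GenusConfig(**g) for g in d["genera"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunityConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthRecord:
    """Generating truth for one simulated community."""

    samples: dict[str, dict]         # sample_id -> species/genus/region/guild
    pairs: dict[str, dict]           # pair_id -> tau_ma, tau_subst, theta, guild
    species_members: dict[str, list[str]]
    seed: int
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


def _mutate(rng: np.random.Generator, seq: np.ndarray, blen_u: float) -> np.ndarray:
    out = seq.copy()
    for _ in range(rng.poisson(blen_u * out.size)):
        pos = rng.integers(out.size)
        out[pos] = (out[pos] + 1 + rng.integers(3)) % 4
    return out


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _simulate_marker(config: CommunityConfig, rng: np.random.Generator,
                     L: int, rate_mult: float):
    """One marker's sequences for the whole community; returns {sample_id: codes}."""
    r = config.clock_rate * rate_mult  # pairwise substitutions per site per Myr
    theta = config.theta * rate_mult
    n_ind = config.n_individuals
    seqs: dict[str, np.ndarray] = {}
    membership: dict[str, list[str]] = {}
    empty = np.empty(0, dtype=np.uint8)

    def species_id(genus: str, region: Region, k: int) -> str:
        return f"{genus}_{'C' if region == Region.CN else 'A'}{k}"

    def emit(sp_id: str, codes: np.ndarray) -> None:
        ids = [f"{sp_id}_{i + 1:02d}" for i in range(codes.shape[0])]
        membership[sp_id] = ids
        for sid, row in zip(ids, codes):
            seqs[sid] = row

    for genus in config.genera:
        root = rng.integers(0, 4, size=L).astype(np.uint8)
        has_pair = genus.cross_sisters and genus.n_species_cn and genus.n_species_aus
        extras: list[tuple[Region, int]] = []
        for k in range(1 if has_pair else 0, genus.n_species_cn):
            extras.append((Region.CN, k + 1))
        for k in range(1 if has_pair else 0, genus.n_species_aus):
            extras.append((Region.AUS, k + 1))
        depths = [config.congener_base_ma + i * config.congener_step_ma
                  for i in range(len(extras))]
        # backbone: deepest join first, mutating toward the shallow end
        backbone = root
        node_seqs: list[np.ndarray] = []
        prev_depth = depths[-1] if depths else None
        for depth in reversed(depths):
            backbone = _mutate(rng, backbone, (prev_depth - depth) / 2.0 * r)
            node_seqs.append(backbone)
            prev_depth = depth
        node_seqs.reverse()  # node_seqs[i] is the backbone node at depths[i]
        for (region, k), depth, node in zip(extras, depths, node_seqs):
            codes = _kernels.seeded_pair_seqs(
                _kernel_seed(rng), theta, theta, theta, 0.0, n_ind, 0, L,
                node, depth / 2.0 * r,
            )
            emit(species_id(genus.name, region, k), codes)
        if has_pair:
            tau_ma = config.tau_for(genus)
            if depths:
                anchor_ma, anchor_seq = depths[0], node_seqs[0]
            else:
                anchor_ma, anchor_seq = tau_ma, root  # pair is the whole genus
            codes = _kernels.seeded_pair_seqs(
                _kernel_seed(rng), theta, theta, theta, tau_ma * r,
                n_ind, n_ind, L, anchor_seq, anchor_ma / 2.0 * r,
            )
            emit(species_id(genus.name, Region.CN, 1), codes[:n_ind])
            emit(species_id(genus.name, Region.AUS, 1), codes[n_ind:])
    return seqs, membership


def simulate_community(
    config: CommunityConfig, outdir: str | Path | None = None
) -> tuple[CommunityDataset, TruthRecord]:
    """Generate a full community dataset plus its truth record.

    Fully reproducible under ``config.seed``; when *outdir* is given, writes
    ``coi.fasta``, ``its2.fasta``, ``metadata.tsv`` and ``truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    coi_seqs, members = _simulate_marker(config, rng, config.L_coi, 1.0)
    its2_seqs, _ = _simulate_marker(config, rng, config.L_its2,
                                    config.its2_rate_multiplier)

    sample_truth: dict[str, dict] = {}
    metadata: list[WaspRecord] = []
    guild_by_genus = {g.name: g.guild for g in config.genera}
    for sp_id, ids in members.items():
        genus, tag = sp_id.rsplit("_", 1)
        region = Region.CN if tag.startswith("C") else Region.AUS
        for sid in ids:
            sample_truth[sid] = dict(
                species=sp_id, genus=genus, region=region.value,
                guild=guild_by_genus[genus].value,
            )
            metadata.append(
                WaspRecord(sid, genus, region, guild_by_genus[genus], sp_id)
            )

    # a fraction of samples lose one marker at random
    all_ids = sorted(sample_truth)
    n_missing = int(round(config.missing_fraction * len(all_ids)))
    lose = rng.choice(len(all_ids), size=n_missing, replace=False) if n_missing else []
    for i in lose:
        sid = all_ids[int(i)]
        (coi_seqs if rng.random() < 0.5 else its2_seqs).pop(sid, None)

    def to_alignment(seqmap: dict[str, np.ndarray], marker: Marker) -> MarkerAlignment:
        recs = [
            SequenceRecord(sid, marker, _DECODE[seqmap[sid]].tobytes().decode())
            for sid in sorted(seqmap)
        ]
        return MarkerAlignment(marker, recs)

    dataset = build_dataset(
        {Marker.COI: to_alignment(coi_seqs, Marker.COI),
         Marker.ITS2: to_alignment(its2_seqs, Marker.ITS2)},
        metadata,
    )
    pairs = {}
    for g in config.genera:
        if g.cross_sisters and g.n_species_cn and g.n_species_aus:
            tau_ma = config.tau_for(g)
            pairs[g.name] = dict(
                species_cn=f"{g.name}_C1", species_aus=f"{g.name}_A1",
                tau_ma=tau_ma, tau_subst=tau_ma * config.clock_rate,
                theta=config.theta, guild=g.guild.value,
            )
    truth = TruthRecord(
        samples=sample_truth, pairs=pairs,
        species_members={k: list(v) for k, v in members.items()},
        seed=config.seed, config_hash=config.config_hash(),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta_alignment(dataset.alignments[Marker.COI], outdir / "coi.fasta")
        write_fasta_alignment(dataset.alignments[Marker.ITS2], outdir / "its2.fasta")
        with open(outdir / "metadata.tsv", "w") as fh:
            fh.write("sample_id\tgenus\tregion\tguild\tspecies_label\n")
            for rec in metadata:
                fh.write(
                    f"{rec.sample_id}\t{rec.genus}\t{rec.region.value}"
                    f"\t{rec.guild.value}\t{rec.species_label or ''}\n"
                )
        (outdir / "truth.json").write_text(truth.to_json())
    return dataset, truth


def sister_pairs_from_truth(
    dataset: CommunityDataset, truth: TruthRecord, min_per_side: int = 2
) -> list[SisterPairDataset]:
    """COI sister-pair datasets for the hABC, taken from the generating truth."""
    coi = dataset.alignments[Marker.COI]
    by_id = {r.sample_id: r.residues for r in coi.records}
    out = []
    for pair_id in sorted(truth.pairs):
        info = truth.pairs[pair_id]
        cn = [by_id[s] for s in truth.species_members[info["species_cn"]] if s in by_id]
        aus = [by_id[s] for s in truth.species_members[info["species_aus"]] if s in by_id]
        if len(cn) >= min_per_side and len(aus) >= min_per_side:
            out.append(SisterPairDataset(pair_id, Guild(info["guild"]), cn, aus))
    return out


@dataclass
class Scorecard:
    """Recovery scores of pipeline outputs against the generating truth."""

    species_precision: float | None  # None when no co-predicted pair exists
    species_recall: float
    n_true_species: int
    n_predicted_species: int
    tau_errors_ma: dict[str, float] = field(default_factory=dict)
    model_correct: bool | None = None

    @property
    def exact(self) -> bool:
        return self.species_precision == 1.0 and self.species_recall == 1.0


def truth_check(
    hypotheses: list[SpeciesHypothesis],
    truth: TruthRecord,
    tau_estimates_ma: dict[str, float] | None = None,
    chosen_model: str | None = None,
    true_model: str | None = None,
) -> Scorecard:
    """Score delimited species (and optionally dating / model choice) vs truth.

    Precision and recall are pair-counting scores over co-clustered sample
    pairs: precision = co-predicted pairs that are truly conspecific,
    recall = truly conspecific pairs that are co-predicted.  An empty output
    has undefined precision (None) and recall 0.
    """
    unknown = [m for h in hypotheses for m in h.members if m not in truth.samples]
    if unknown:
        raise ValueError(f"sample ids absent from truth: {sorted(unknown)[:5]} ...")
    pred_pairs: set[frozenset[str]] = set()
    for h in hypotheses:
        for i, a in enumerate(h.members):
            for b in h.members[i + 1:]:
                pred_pairs.add(frozenset((a, b)))
    true_pairs: set[frozenset[str]] = set()
    for ids in truth.species_members.values():
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                true_pairs.add(frozenset((a, b)))
    tp = len(pred_pairs & true_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else None
    recall = tp / len(true_pairs) if true_pairs else 1.0
    tau_err = {}
    if tau_estimates_ma:
        for pid, est in tau_estimates_ma.items():
            if pid in truth.pairs:
                tau_err[pid] = est - truth.pairs[pid]["tau_ma"]
    return Scorecard(
        species_precision=precision,
        species_recall=recall,
        n_true_species=len(truth.species_members),
        n_predicted_species=len(hypotheses),
        tau_errors_ma=tau_err,
        model_correct=(chosen_model == true_model) if chosen_model and true_model else None,
    )
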