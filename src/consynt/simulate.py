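"""Synthetic dataset generation for end-to-end, download-free testing.

Two kinds of fixtures are produced:

* :func:`generate` / :func:`build_dataset` — a fully parameterized random
  dataset: a primary (human-like) gene universe with counterparts in a target
  species at configurable rates, phenotype annotations with per-category
  enrichment odds for the risk set, a Bernoulli interaction graph with
  elevated within-risk-set density, and planted co-localized gene blocks
  conserved between the two genomes.  Everything is reproducible from one
  master seed; each output draws from its own child stream so adding an
  output never perturbs the others.

* :func:`paper_count_fixture` — a deterministic dataset whose marginal counts
  equal the printed tallies of the study this pipeline reproduces
  (276/336 and 324/336 counterparts; 129/119/50 of 276 phenotype counts;
  genome backgrounds 12345/20310, 14623/20479, 4645/19727, 264/2445,
  1876/18496), with synthetic companion coordinates and interaction graph so
  every pipeline stage has input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import StudyPoint, _random_graph_arrays
from .counterparts import (
    STATUS_CURATED,
    STATUS_NONE,
    CounterpartAssignment,
)
from .io import (
    GeneRecord,
    InteractionGraph,
    PhenotypeAnnotation,
    RiskGeneSet,
    write_edge_list,
    write_gene_coordinates,
    write_phenotype_table,
)
from .synteny import BlockCriteria, SyntenyBlockCandidate, evaluate_block, find_candidates

logger = logging.getLogger(__name__)

# category -> representative phenotype term emitted by the generator; chosen
# so that re-deriving flags from the terms recovers the sampled category
CATEGORY_TERMS = {
    "lethal": "lethal",
    "sterile": "sterile",
    "lifespan": "extended life span",
    "embryonic": "embryonic development variant",
    "development": "development variant",
    "locomotion": "locomotion variant",
    "neurotransmitter": "neurotransmitter level variant",
}

# base rates follow the genome-background tallies of the study reproduced
# here (lethal 264/2445, life span 1876/18496, essential 4645/19727 with
# sterile filling the essential remainder); odds move the risk set to the
# printed risk-set rates (129, 119, 50 of 276)
DEFAULT_BASE_RATES = {
    "lethal": 0.108,
    "sterile": 0.143,
    "lifespan": 0.101,
    "embryonic": 0.08,
    "development": 0.15,
    "locomotion": 0.12,
    "neurotransmitter": 0.03,
}
DEFAULT_RISK_ODDS = {
    "lethal": 6.26,
    "sterile": 0.41,
    "lifespan": 1.96,
    "embryonic": 1.5,
    "development": 1.5,
    "locomotion": 1.5,
    "neurotransmitter": 1.5,
}


@dataclass
class SyntheticDatasetSpec:
    """All generator parameters; identical spec + seed => identical outputs."""

    seed: int = 0
    n_genes_primary: int = 5000
    n_chromosomes_primary: int = 23
    n_chromosomes_secondary: int = 25
    chromosome_length_bp: int = 120_000_000
    conservation_rate: float = 0.608
    risk_conservation_rate: float = 0.821
    risk_set_size: int = 336
    phenotype_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    phenotype_risk_odds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_ODDS)
    )
    graph_p_background: float = 0.0194
    graph_p_within_risk: float = 0.0388
    planted_blocks: list[tuple[int, int]] = field(
        default_factory=lambda: [(4, 200_000)] * 5
    )

    def __post_init__(self) -> None:
        for name in ("conservation_rate", "risk_conservation_rate",
                     "graph_p_background", "graph_p_within_risk"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for cat, p in self.phenotype_base_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"base rate for {cat} outside [0, 1]")
        for cat, o in self.phenotype_risk_odds.items():
            if o < 0:
                raise ValueError(f"odds for {cat} must be >= 0")
        n_block = sum(n for n, _ in self.planted_blocks)
        if self.risk_set_size > self.n_genes_primary:
            raise ValueError("risk_set_size exceeds n_genes_primary")
        if n_block > self.risk_set_size:
            raise ValueError("planted blocks exceed the risk set size")


@dataclass
class SyntheticDataset:
    """In-memory realization of a SyntheticDatasetSpec."""

    spec: SyntheticDatasetSpec
    primary_records: list[GeneRecord]
    secondary_records: list[GeneRecord]
    counterparts: dict[str, str]  # primary gene -> secondary gene
    risk_set: RiskGeneSet
    phenotypes: list[PhenotypeAnnotation]
    graph: InteractionGraph
    planted_block_genes: list[list[str]]

    def assignments(self, target_species: str = "target") -> list[CounterpartAssignment]:
        out = []
        for g in self.risk_set.members:
            cp = self.counterparts.get(g)
            out.append(
                CounterpartAssignment(
                    human_gene=g,
                    target_species=target_species,
                    counterpart_gene=cp,
                    status=STATUS_CURATED if cp is not None else STATUS_NONE,
                    evidence=["curated-lookup"] if cp is not None else [],
                )
            )
        return out


def _risk_rate(base: float, odds: float) -> float:
    """Move a base probability by an odds multiplier."""
    return odds * base / (1.0 - base + odds * base)


def _place_items(
    lengths: list[int], chrom_len: int, rng: np.random.Generator, offset: int = 0
) -> list[int]:
    """Uniform non-overlapping placement: 1-based starts for each item length."""
    total = sum(lengths)
    free = chrom_len - total
    if free < 0:
        raise ValueError(
            f"infeasible placement: {total} bp of items on a {chrom_len} bp chromosome"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = []
    consumed = 0
    for cut, length in zip(cuts, lengths):
        starts.append(offset + int(cut) + consumed + 1)
        consumed += length
    return starts


def _place_genome(
    gene_ids: list[str],
    gene_chroms: np.ndarray,
    gene_lengths: np.ndarray,
    blocks: list[tuple[list[str], int, int]],  # (gene ids, chromosome, span)
    n_chromosomes: int,
    chromosome_length: int,
    species: str,
    rng: np.random.Generator,
) -> list[GeneRecord]:
    """Place scattered genes and block windows without overlap, then genes
    within their windows."""
    records: dict[str, GeneRecord] = {}
    blocks_by_chrom: dict[int, list[tuple[list[str], int]]] = {}
    for genes, chrom, span in blocks:
        blocks_by_chrom.setdefault(chrom, []).append((genes, span))

    for c in range(n_chromosomes):
        idx = np.flatnonzero(gene_chroms == c)
        items: list[tuple[str, int]] = [
            (gene_ids[i], int(gene_lengths[i])) for i in idx
        ]
        chrom_blocks = blocks_by_chrom.get(c, [])
        all_lengths = [ln for _, ln in items] + [span for _, span in chrom_blocks]
        starts = _place_items(all_lengths, chromosome_length, rng)
        chrom_name = f"chr{c + 1}"
        for (gid, ln), start in zip(items, starts[: len(items)]):
            records[gid] = GeneRecord(
                gene_id=gid, symbol=gid, species=species,
                chromosome=chrom_name, start=start, end=start + ln - 1,
            )
        for (genes, span), win_start in zip(chrom_blocks, starts[len(items):]):
            inner_lengths = [
                int(rng.integers(2_000, min(20_000, span // len(genes))))
                for _ in genes
            ]
            inner_starts = _place_items(inner_lengths, span, rng, offset=win_start - 1)
            for gid, s, ln in zip(genes, inner_starts, inner_lengths):
                records[gid] = GeneRecord(
                    gene_id=gid, symbol=gid, species=species,
                    chromosome=chrom_name, start=s, end=s + ln - 1,
                )
    order = list(gene_ids) + [g for genes, _, _ in blocks for g in genes]
    return [records[g] for g in order]


def build_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Realize a spec in memory (no files written)."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_coord_p, rng_coord_s, rng_cons, rng_pheno, rng_edges, rng_risk = (
        np.random.default_rng(s) for s in streams
    )

    n = spec.n_genes_primary
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    n_block = sum(k for k, _ in spec.planted_blocks)

    # the last n_block genes are the planted ones; risk = planted + random others
    planted_ids: list[list[str]] = []
    cursor = n - n_block
    for k, _span in spec.planted_blocks:
        planted_ids.append(gene_ids[cursor:cursor + k])
        cursor += k
    scattered_ids = gene_ids[: n - n_block]
    extra_risk = spec.risk_set_size - n_block
    risk_extra = list(
        rng_risk.choice(np.asarray(scattered_ids, dtype=object), extra_risk, replace=False)
    )
    risk_members = [g for block in planted_ids for g in block] + risk_extra
    risk_set = RiskGeneSet(label="synthetic_risk", members=risk_members)
    risk_lookup = set(risk_members)

    # primary genome
    gene_chroms = rng_coord_p.integers(0, spec.n_chromosomes_primary, size=n - n_block)
    gene_lengths = rng_coord_p.integers(2_000, 20_000, size=n - n_block)
    block_placements = [
        (block, int(rng_coord_p.integers(0, spec.n_chromosomes_primary)), span)
        for block, (_k, span) in zip(planted_ids, spec.planted_blocks)
    ]
    primary_records = _place_genome(
        scattered_ids, gene_chroms, gene_lengths, block_placements,
        spec.n_chromosomes_primary, spec.chromosome_length_bp, "primary", rng_coord_p,
    )

    # conservation: planted genes always conserved co-chromosomally
    counterparts: dict[str, str] = {}
    for gid in scattered_ids:
        rate = (
            spec.risk_conservation_rate
            if gid in risk_lookup
            else spec.conservation_rate
        )
        if rng_cons.random() < rate:
            counterparts[gid] = f"t-{gid}"
    for block in planted_ids:
        for gid in block:
            counterparts[gid] = f"t-{gid}"

    # secondary genome: conserved scattered genes anywhere, planted blocks
    # kept co-chromosomal within a window
    conserved_scattered = [g for g in scattered_ids if g in counterparts]
    sec_ids = [counterparts[g] for g in conserved_scattered]
    sec_chroms = rng_coord_s.integers(
        0, spec.n_chromosomes_secondary, size=len(sec_ids)
    )
    sec_lengths = rng_coord_s.integers(2_000, 20_000, size=len(sec_ids))
    sec_blocks = [
        (
            [counterparts[g] for g in block],
            int(rng_coord_s.integers(0, spec.n_chromosomes_secondary)),
            span,
        )
        for block, (_k, span) in zip(planted_ids, spec.planted_blocks)
    ]
    secondary_records = _place_genome(
        sec_ids, sec_chroms, sec_lengths, sec_blocks,
        spec.n_chromosomes_secondary, spec.chromosome_length_bp, "secondary",
        rng_coord_s,
    )

    # phenotypes for genes with counterparts
    phenotypes: list[PhenotypeAnnotation] = []
    conserved_all = [g for g in gene_ids if g in counterparts]
    for gid in conserved_all:
        is_risk = gid in risk_lookup
        terms = []
        for cat, base in spec.phenotype_base_rates.items():
            p = _risk_rate(base, spec.phenotype_risk_odds.get(cat, 1.0)) if is_risk else base
            if rng_pheno.random() < p:
                terms.append(CATEGORY_TERMS.get(cat, cat))
        phenotypes.append(PhenotypeAnnotation(gene_id=gid, terms=terms))

    # interaction graph over the whole primary universe
    risk_index = np.asarray(
        sorted(gene_ids.index(g) for g in risk_members), dtype=np.int64
    )
    u, v = _random_graph_arrays(
        n, spec.graph_p_background, rng_edges,
        risk_index=risk_index, p_within=spec.graph_p_within_risk,
    )
    graph = InteractionGraph.from_arrays(gene_ids, u, v)

    return SyntheticDataset(
        spec=spec,
        primary_records=primary_records,
        secondary_records=secondary_records,
        counterparts=counterparts,
        risk_set=risk_set,
        phenotypes=phenotypes,
        graph=graph,
        planted_block_genes=planted_ids,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_lookup(counterparts: dict[str, str], genes: list[str], path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("human_gene\ttarget_gene\n")
        for g in genes:
            fh.write(f"{g}\t{counterparts.get(g, 'None')}\n")


def _write_risk(risk_set: RiskGeneSet, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("symbol\n")
        for g in risk_set.members:
            fh.write(f"{g}\n")


def generate(spec: SyntheticDatasetSpec, out_dir: str | Path) -> dict:
    """Realize a spec and write all fixture files; returns a checksum manifest."""
    ds = build_dataset(spec)  # placement errors raised before any file is written
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_gene_coordinates(ds.primary_records, out / "primary.bed", "BED6")
    write_gene_coordinates(ds.secondary_records, out / "secondary.bed", "BED6")
    _write_lookup(
        ds.counterparts, [r.gene_id for r in ds.primary_records], out / "counterparts.tsv"
    )
    write_phenotype_table(ds.phenotypes, out / "phenotypes.tsv")
    write_edge_list(ds.graph, out / "edges.tsv")
    _write_risk(ds.risk_set, out / "risk.tsv")

    files = [
        "primary.bed", "secondary.bed", "counterparts.tsv",
        "phenotypes.tsv", "edges.tsv", "risk.tsv",
    ]
    manifest = {
        "spec": asdict(spec),
        "files": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# deterministic printed-count fixture


# printed genome backgrounds: counterpart carriers K of N genes
CONSERVATION_BACKGROUNDS = {
    "celegans": (12345, 20310),
    "zebrafish": (14623, 20479),
}
# printed phenotype backgrounds: note the denominators differ per category
PHENOTYPE_BACKGROUNDS = {
    "essential": (4645, 19727),
    "lethal": (264, 2445),
    "lifespan": (1876, 18496),
}
# printed per-study (conservation %, links per gene) pairs; the conservation
# values are the integer percentages as plotted (257/344, 276/336, 199/230)
STUDY_POINTS = [
    ("schizophrenia", 75.0, 8.0),
    ("mdd", 82.0, 13.0),
    ("bipolar", 87.0, 22.0),
]

_FIXTURE_GRAPH_SEED = 20210715  # fixed: part of the fixture definition


@dataclass
class PaperCountFixture:
    """Deterministic dataset reproducing the study's printed marginal counts."""

    risk_set: RiskGeneSet
    curated: dict[str, dict[str, str]]  # species -> human gene -> counterpart
    phenotypes: list[PhenotypeAnnotation]
    primary_records: list[GeneRecord]
    secondary_records: list[GeneRecord]  # zebrafish-side coordinates
    graph: InteractionGraph
    universe: list[str]
    backgrounds_conservation: dict[str, tuple[int, int]]
    backgrounds_phenotype: dict[str, tuple[int, int]]
    study_points: list[StudyPoint]

    def assignments(self, species: str) -> list[CounterpartAssignment]:
        lookup = self.curated[species]
        return [
            CounterpartAssignment(
                human_gene=g,
                target_species=species,
                counterpart_gene=lookup.get(g),
                status=STATUS_CURATED if g in lookup else STATUS_NONE,
                evidence=["curated-lookup"] if g in lookup else [],
            )
            for g in self.risk_set.members
        ]


def paper_count_fixture(out_dir: str | Path | None = None) -> PaperCountFixture:
    """Build (and optionally write) the printed-count fixture.

    Counterpart tables carry exactly 276/336 (C. elegans) and 324/336
    (zebrafish) counterparts; phenotype terms give exactly 129 essential,
    119 lethal and 50 life-span genes among the 276 with counterparts.
    Coordinates place five tight blocks of conserved risk genes (synthetic
    companions, not printed data); the interaction graph doubles the
    within-risk edge density over background so the risk set's links per gene
    sits near twice the random-set level.
    """
    n_risk, n_universe = 336, 2000
    universe = [f"HG{i + 1:04d}" for i in range(n_universe)]
    risk_genes = universe[:n_risk]
    risk_set = RiskGeneSet(label="mdd_risk", members=list(risk_genes))

    curated = {
        "celegans": {g: f"cel-{g}" for g in risk_genes[:276]},
        "zebrafish": {g: f"dr-{g}" for g in risk_genes[:324]},
    }

    # phenotype table over the 276 genes with C. elegans counterparts:
    # genes 1..119 lethal, 120..129 sterile (essential = 129), 1..50 also
    # affect life span, the rest carry a benign locomotion term
    phenotypes: list[PhenotypeAnnotation] = []
    for i in range(276):
        terms: list[str] = []
        if i < 119:
            terms.append("lethal")
        elif i < 129:
            terms.append("sterile")
        if i < 50:
            terms.append("shortened life span")
        if not terms:
            terms.append("locomotion variant")
        phenotypes.append(PhenotypeAnnotation(gene_id=risk_genes[i], terms=terms))

    # primary coordinates: risk genes spaced 7 Mb apart across 23 chromosomes
    # (no chance clusters at a 1 Mb gap), plus 5 planted 4-gene blocks of
    # conserved, mostly-lethal genes (indices 100..119) at tight spacing
    primary_records: list[GeneRecord] = []
    block_indices = [list(range(100 + 4 * b, 104 + 4 * b)) for b in range(5)]
    in_block = {i for block in block_indices for i in block}
    for i in range(n_risk):
        if i in in_block:
            continue
        chrom = f"chr{i % 23 + 1}"
        start = 1_000_000 + (i // 23) * 7_000_000
        primary_records.append(
            GeneRecord(
                gene_id=risk_genes[i], symbol=risk_genes[i], species="human",
                chromosome=chrom, start=start, end=start + 9_999,
            )
        )
    for b, block in enumerate(block_indices):
        for j, i in enumerate(block):
            start = 110_000_000 + j * 50_000
            primary_records.append(
                GeneRecord(
                    gene_id=risk_genes[i], symbol=risk_genes[i], species="human",
                    chromosome=f"chr{b + 1}", start=start, end=start + 9_999,
                )
            )
    primary_records.sort(key=lambda r: (r.chromosome, r.start))

    # zebrafish-side coordinates for the 324 counterparts; each planted
    # block's counterparts share one chromosome
    secondary_records: list[GeneRecord] = []
    for i in range(324):
        gid = f"dr-{risk_genes[i]}"
        if i in in_block:
            b = (i - 100) // 4
            chrom = f"chr{b + 1}"
            start = 100_000_000 + ((i - 100) % 4) * 40_000
        else:
            chrom = f"chr{i % 25 + 1}"
            start = 1_000_000 + (i // 25) * 5_000_000
        secondary_records.append(
            GeneRecord(
                gene_id=gid, symbol=gid, species="zebrafish",
                chromosome=chrom, start=start, end=start + 7_999,
            )
        )
    secondary_records.sort(key=lambda r: (r.chromosome, r.start))

    # interaction graph: background density tuned so random 336-gene sets
    # average ~6.5 links per gene, doubled inside the risk set
    rng = np.random.default_rng(_FIXTURE_GRAPH_SEED)
    risk_index = np.arange(n_risk, dtype=np.int64)
    u, v = _random_graph_arrays(
        n_universe, 0.0194, rng, risk_index=risk_index, p_within=0.0388
    )
    graph = InteractionGraph.from_arrays(universe, u, v)

    fixture = PaperCountFixture(
        risk_set=risk_set,
        curated=curated,
        phenotypes=phenotypes,
        primary_records=primary_records,
        secondary_records=secondary_records,
        graph=graph,
        universe=universe,
        backgrounds_conservation=dict(CONSERVATION_BACKGROUNDS),
        backgrounds_phenotype=dict(PHENOTYPE_BACKGROUNDS),
        study_points=[StudyPoint(*p) for p in STUDY_POINTS],
    )
    if out_dir is not None:
        _write_paper_fixture(fixture, Path(out_dir))
    return fixture


def _write_paper_fixture(fixture: PaperCountFixture, out: Path) -> dict:
    import yaml

    out.mkdir(parents=True, exist_ok=True)
    _write_risk(fixture.risk_set, out / "risk.tsv")
    for species, lookup in fixture.curated.items():
        _write_lookup(lookup, fixture.risk_set.members, out / f"counterparts_{species}.tsv")
    write_phenotype_table(fixture.phenotypes, out / "phenotypes.tsv")
    write_gene_coordinates(fixture.primary_records, out / "primary.bed", "BED6")
    write_gene_coordinates(fixture.secondary_records, out / "secondary.bed", "BED6")
    write_edge_list(fixture.graph, out / "edges.tsv")
    with open(out / "universe.tsv", "wt", encoding="utf-8") as fh:
        fh.write("gene_id\n")
        for g in fixture.universe:
            fh.write(f"{g}\n")

    config = {
        "seed": 1,
        "output_dir": str(out / "reports"),
        "inputs": {
            "risk_set": str(out / "risk.tsv"),
            "edge_list": str(out / "edges.tsv"),
            "phenotypes": str(out / "phenotypes.tsv"),
            "coordinates_primary": str(out / "primary.bed"),
            "coordinates_secondary": str(out / "secondary.bed"),
            "gene_universe": str(out / "universe.tsv"),
            "counterparts": {
                species: str(out / f"counterparts_{species}.tsv")
                for species in fixture.curated
            },
        },
        "backgrounds": {
            "conservation": {
                sp: list(kn) for sp, kn in fixture.backgrounds_conservation.items()
            },
            "phenotypes": {
                cat: list(kn) for cat, kn in fixture.backgrounds_phenotype.items()
            },
        },
        "studies": [
            {
                "label": p.study_label,
                "conservation_pct": p.conservation_pct,
                "links_per_gene": p.links_per_gene,
            }
            for p in fixture.study_points
            if p.study_label != "mdd"  # this-study point is recomputed
        ],
        "correlation": {"species": "celegans"},
        "phenotype_species": "celegans",
        "synteny": {"secondary_species": "zebrafish"},
    }
    with open(out / "config.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config


# ---------------------------------------------------------------------------
# planted-block recovery experiment


@dataclass(frozen=True)
class BlockRecoveryResult:
    n_seeds: int
    recovered_fraction: float  # planted blocks fully contained in a candidate
    mean_candidates: float
    mean_accepted_planted: float
    mean_accepted_shuffled: float


def planted_block_experiment(
    n_seeds: int = 50,
    seed: int = 0,
    detection_max_gap_bp: int = 300_000,
    criteria: BlockCriteria | None = None,
    n_scattered: int = 300,
    n_chromosomes: int = 23,
    chromosome_length_bp: int = 130_000_000,
) -> BlockRecoveryResult:
    """Recovery of planted blocks vs a coordinate-shuffling permutation null.

    Each replicate plants five 4-gene blocks (within 200 kb) among
    ``n_scattered`` uniformly placed risk genes, detects candidates, evaluates
    them against the secondary genome, then permutes the coordinate-to-gene
    assignment and re-runs the evaluation.  Shuffling preserves positional
    clustering but destroys the planted genes' conserved co-chromosomal
    placement, so accepted blocks on shuffled data measure the chance level.
    """
    crit = criteria or BlockCriteria(
        min_genes=3,
        max_gap_bp=detection_max_gap_bp,
        max_secondary_chromosomes=2,
        min_counterpart_coverage=0.75,
    )
    rng = np.random.default_rng(seed)
    n_recovered = 0
    n_planted_total = 0
    total_candidates = 0
    accepted_planted = 0
    accepted_shuffled = 0
    for rep in range(n_seeds):
        spec = SyntheticDatasetSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_genes_primary=n_scattered + 20,
            risk_set_size=n_scattered + 20,
            n_chromosomes_primary=n_chromosomes,
            n_chromosomes_secondary=25,
            chromosome_length_bp=chromosome_length_bp,
            planted_blocks=[(4, 200_000)] * 5,
            graph_p_background=0.0,
            graph_p_within_risk=0.0,
        )
        ds = build_dataset(spec)
        coords = {r.gene_id: r for r in ds.primary_records}
        risk_coords = [coords[g] for g in ds.risk_set.members]
        assignments = ds.assignments()

        candidates = find_candidates(risk_coords, crit.max_gap_bp, crit.min_genes)
        total_candidates += len(candidates)
        for block in ds.planted_block_genes:
            n_planted_total += 1
            if any(set(block) <= set(c.genes) for c in candidates):
                n_recovered += 1
        blocks = [
            evaluate_block(c, assignments, ds.secondary_records, ds.phenotypes, crit)
            for c in candidates
        ]
        accepted_planted += sum(b.accepted for b in blocks)

        # permutation null: shuffle which gene sits at which locus
        perm = rng.permutation(len(risk_coords))
        shuffled = [
            GeneRecord(
                gene_id=risk_coords[i].gene_id,
                symbol=risk_coords[i].symbol,
                species=risk_coords[i].species,
                chromosome=risk_coords[int(j)].chromosome,
                start=risk_coords[int(j)].start,
                end=risk_coords[int(j)].end,
                strand=risk_coords[int(j)].strand,
            )
            for i, j in enumerate(perm)
        ]
        shuffled_candidates = find_candidates(shuffled, crit.max_gap_bp, crit.min_genes)
        shuffled_blocks = [
            evaluate_block(c, assignments, ds.secondary_records, ds.phenotypes, crit)
            for c in shuffled_candidates
        ]
        accepted_shuffled += sum(b.accepted for b in shuffled_blocks)

    return BlockRecoveryResult(
        n_seeds=n_seeds,
        recovered_fraction=n_recovered / n_planted_total,
        mean_candidates=total_candidates / n_seeds,
        mean_accepted_planted=accepted_planted / n_seeds,
        mean_accepted_shuffled=accepted_shuffled / n_seeds,
    )
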