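"""Detection and evaluation of co-localized risk-gene blocks across genomes.

Candidates are found by single-linkage clustering of risk-gene intervals
along each chromosome of the primary genome: position-sorted neighbors join a
cluster while the boundary-to-boundary gap stays within ``max_gap_bp``.  A
candidate is promoted to an accepted syntenic block when enough of its genes
have counterparts in the secondary genome and those counterparts stay on few
secondary chromosomes.  Shared phenotypes are tallied as every category
carried by at least two block genes, in "Term k/n" notation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .counterparts import CounterpartAssignment
from .io import GeneRecord, PhenotypeAnnotation
from .phenotypes import FLAG_CATEGORIES, PhenotypeVocabulary, derive_flags

logger = logging.getLogger(__name__)


@dataclass
class SyntenyBlockCandidate:
    """A run of co-localized risk genes on one primary-genome chromosome."""

    genes: list[str]  # ordered by primary-genome start
    chromosome_primary: str
    span_bp: int
    band_label: str | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class SyntenyBlock:
    candidate: SyntenyBlockCandidate
    chromosomes_secondary: set[str]
    counterpart_coverage: float
    shared_phenotypes: list[tuple[str, int, int]]
    functional_annotations: list[str] = field(default_factory=list)
    accepted: bool = False

    @property
    def genes(self) -> list[str]:
        return self.candidate.genes


@dataclass(frozen=True)
class BlockCriteria:
    """Acceptance criteria; deliberately parameterized, not hard-coded."""

    min_genes: int = 3
    max_gap_bp: int = 1_000_000
    max_secondary_chromosomes: int = 5
    min_counterpart_coverage: float = 0.5


def find_candidates(
    risk_coords: Sequence[GeneRecord],
    max_gap_bp: int,
    min_genes: int = 3,
) -> list[SyntenyBlockCandidate]:
    """Single-linkage clustering of risk-gene intervals along each chromosome.

    The gap is measured between interval boundaries (end of the rightmost
    interval seen so far to the start of the next gene); clusters with at
    least ``min_genes`` genes are returned ordered by (chromosome, start).
    Each gene belongs to at most one candidate.
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in risk_coords:
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    candidates: list[tuple[str, int, SyntenyBlockCandidate]] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
        cluster: list[GeneRecord] = []
        max_end = 0

        def flush() -> None:
            if len(cluster) >= min_genes:
                start = min(r.start for r in cluster)
                end = max(r.end for r in cluster)
                candidates.append(
                    (
                        chrom,
                        start,
                        SyntenyBlockCandidate(
                            genes=[r.gene_id for r in cluster],
                            chromosome_primary=chrom,
                            span_bp=end - start,
                        ),
                    )
                )

        for rec in recs:
            if cluster and rec.start - max_end > max_gap_bp:
                flush()
                cluster = []
            cluster.append(rec)
            max_end = max(max_end, rec.end)
        flush()
    candidates.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in candidates]


def evaluate_block(
    candidate: SyntenyBlockCandidate,
    counterparts: Iterable[CounterpartAssignment],
    secondary_coords: Sequence[GeneRecord],
    phenotypes: Iterable[PhenotypeAnnotation],
    criteria: BlockCriteria = BlockCriteria(),
    vocabulary: PhenotypeVocabulary | None = None,
    functional_annotations: Iterable[str] = (),
) -> SyntenyBlock:
    """Score a candidate against the secondary genome and phenotype data.

    Secondary chromosomes are collected from the coordinates of the genes'
    counterparts; acceptance requires counterpart coverage at or above the
    threshold and a chromosome spread at or below the maximum.  Shared
    phenotypes report every flag category carried by >= 2 block genes as
    ``(term, k, n)`` with n the number of block genes with phenotype data.
    """
    vocab = vocabulary or PhenotypeVocabulary.default()
    counterpart_of = {
        a.human_gene: a.counterpart_gene
        for a in counterparts
        if a.has_counterpart
    }
    chrom_of = {r.gene_id: r.chromosome for r in secondary_coords}
    pheno_of = {p.gene_id: p for p in phenotypes}

    secondary_chroms: set[str] = set()
    n_with_counterpart = 0
    for gene in candidate.genes:
        cp = counterpart_of.get(gene)
        if cp is None:
            continue
        n_with_counterpart += 1
        chrom = chrom_of.get(cp)
        if chrom is not None:
            secondary_chroms.add(chrom)
    coverage = n_with_counterpart / candidate.size

    # phenotype sharing: flag categories plus any extra vocabulary category
    annotated = [
        derive_flags(pheno_of[g], vocab) for g in candidate.genes if g in pheno_of
    ]
    total = len(annotated)
    shared: list[tuple[str, int, int]] = []
    carriers = {
        "Lethal": sum(a.lethal for a in annotated),
        "Sterile": sum(a.sterile for a in annotated),
        "Life span": sum(a.lifespan_affected for a in annotated),
    }
    flag_keywords = {kw for kws in vocab.flags.values() for kw in kws}
    keyword_categories: dict[str, list[str]] = {}
    for kws in vocab.stages.values():  # stage keywords stand as terms of their own
        for kw in kws:
            if kw not in flag_keywords:
                keyword_categories[kw.capitalize()] = [kw]
    for cat, kws in vocab.extra.items():
        keyword_categories[cat.replace("_", " ").capitalize()] = kws
    for label, kws in keyword_categories.items():
        carriers[label] = sum(
            any(kw in t.lower() for t in a.terms for kw in kws) for a in annotated
        )
    for term, count in sorted(carriers.items(), key=lambda kv: (-kv[1], kv[0])):
        if count >= 2:
            shared.append((term, count, total))

    accepted = (
        coverage >= criteria.min_counterpart_coverage
        and len(secondary_chroms) <= criteria.max_secondary_chromosomes
        and candidate.size >= criteria.min_genes
    )
    return SyntenyBlock(
        candidate=candidate,
        chromosomes_secondary=secondary_chroms,
        counterpart_coverage=coverage,
        shared_phenotypes=shared,
        functional_annotations=list(functional_annotations),
        accepted=accepted,
    )


REPORT_COLUMNS = [
    "genes",
    "n_genes",
    "location_primary",
    "span_bp",
    "chromosomes_secondary",
    "counterpart_coverage",
    "shared_phenotypes",
    "functional_annotations",
    "accepted",
]


def _format_block_row(block: SyntenyBlock) -> dict:
    cand = block.candidate
    return {
        "genes": "-".join(cand.genes),
        "n_genes": cand.size,
        "location_primary": cand.band_label or cand.chromosome_primary,
        "span_bp": cand.span_bp,
        "chromosomes_secondary": ", ".join(sorted(block.chromosomes_secondary)),
        "counterpart_coverage": round(block.counterpart_coverage, 4),
        "shared_phenotypes": " ".join(
            f"{term} {k}/{n}" for term, k, n in block.shared_phenotypes
        ),
        "functional_annotations": "; ".join(block.functional_annotations),
        "accepted": block.accepted,
    }


def block_report(
    blocks: Sequence[SyntenyBlock],
    path: str | Path | None = None,
    audit_path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate blocks (accepted rows to ``path``, rejected to ``audit_path``).

    Returns the full table (accepted and rejected) in deterministic order:
    by primary chromosome then leftmost gene.
    """
    rows = [_format_block_row(b) for b in blocks]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame = frame.sort_values(
        ["location_primary", "genes"], kind="stable"
    ).reset_index(drop=True)
    accepted_mask = frame["accepted"].astype(bool)
    if path is not None:
        frame[accepted_mask].to_csv(path, sep="\t", index=False)
    if audit_path is not None:
        frame[~accepted_mask].to_csv(audit_path, sep="\t", index=False)
    return frame
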