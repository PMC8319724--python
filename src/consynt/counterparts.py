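"""Cross-species counterpart assignment for a risk-gene set.

A human risk gene gets a counterpart in the target species either from a
curated ortholog lookup (Ensembl/WormBase-style) or, failing that, from
protein homology evidence: a hit is a full counterpart above a percent-identity
threshold provided the alignment covers an extended segment of the shorter
protein and the two proteins are of similar length; a hit in the marginal
20-25% identity band additionally requires convergence — best hits from other
query species landing on the same target gene.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .io import RiskGeneSet, ValidationError

logger = logging.getLogger(__name__)

STATUS_CURATED = "curated_ortholog"
STATUS_SEARCH = "search_counterpart"
STATUS_DISTANT = "distant_homolog"
STATUS_NONE = "none"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class HomologyHit:
    """One protein search hit (query protein vs target-species protein)."""

    query_gene: str
    query_species: str
    subject_gene: str
    percent_identity: float
    alignment_length: int
    query_length: int
    subject_length: int

    # gapped alignments may exceed the ungapped length bound by a small slack
    LENGTH_SLACK: float = field(default=0.2, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_gene}->{self.subject_gene}: identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if min(self.query_length, self.subject_length) < 1:
            raise ValidationError("protein lengths must be >= 1")
        shorter = min(self.query_length, self.subject_length)
        if self.alignment_length > shorter * (1.0 + self.LENGTH_SLACK):
            raise ValidationError(
                f"hit {self.query_gene}->{self.subject_gene}: alignment length "
                f"{self.alignment_length} exceeds shorter protein ({shorter}) "
                "beyond gap slack"
            )

    @property
    def coverage_of_shorter(self) -> float:
        return self.alignment_length / min(self.query_length, self.subject_length)

    @property
    def length_ratio(self) -> float:
        return self.query_length / self.subject_length


@dataclass(frozen=True)
class CounterpartThresholds:
    """Classification thresholds; the distant band is [distant_low, counterpart)."""

    identity_distant_low: float = 20.0
    identity_counterpart: float = 25.0
    min_coverage_of_shorter: float = 0.5
    length_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    min_convergent_species: int = 1

    def __post_init__(self) -> None:
        if self.identity_distant_low >= self.identity_counterpart:
            raise ConfigurationError(
                "identity_distant_low must be < identity_counterpart"
            )
        lo, hi = self.length_ratio_bounds
        if not (0 < lo <= hi):
            raise ConfigurationError("length_ratio_bounds must satisfy 0 < lo <= hi")


@dataclass
class CounterpartAssignment:
    """Resolved counterpart status of one human gene in one target species."""

    human_gene: str
    target_species: str
    counterpart_gene: str | None
    status: str
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == STATUS_NONE) != (self.counterpart_gene is None):
            raise ValidationError(
                f"{self.human_gene}: status {self.status!r} inconsistent with "
                f"counterpart {self.counterpart_gene!r}"
            )

    @property
    def has_counterpart(self) -> bool:
        return self.status != STATUS_NONE


@dataclass(frozen=True)
class ConservationTally:
    """k of n genes with any counterpart (distant homologs count)."""

    with_counterpart: int
    total: int

    @property
    def fraction(self) -> float:
        return self.with_counterpart / self.total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def _passes_geometry(hit: HomologyHit, thresholds: CounterpartThresholds) -> bool:
    lo, hi = thresholds.length_ratio_bounds
    return (
        hit.coverage_of_shorter >= thresholds.min_coverage_of_shorter
        and lo <= hit.length_ratio <= hi
    )


def classify_hit(
    hit: HomologyHit,
    corroborating_hits: list[HomologyHit],
    thresholds: CounterpartThresholds = CounterpartThresholds(),
) -> str:
    """Classify one best hit as search_counterpart / distant_homolog / none.

    ``corroborating_hits`` are hits from *other* query species; convergence
    counts the distinct such species whose hit lands on the same subject gene.
    The lower identity edge of the distant band is inclusive.
    """
    if not _passes_geometry(hit, thresholds):
        return STATUS_NONE
    if hit.percent_identity >= thresholds.identity_counterpart:
        return STATUS_SEARCH
    if hit.percent_identity >= thresholds.identity_distant_low:
        convergent = {
            h.query_species
            for h in corroborating_hits
            if h.subject_gene == hit.subject_gene
            and h.query_species != hit.query_species
        }
        if len(convergent) >= thresholds.min_convergent_species:
            return STATUS_DISTANT
    return STATUS_NONE


def _best_hit(hits: list[HomologyHit]) -> HomologyHit:
    # highest identity, then longest alignment, then lexicographic subject id:
    # a total order, so the winner is independent of input row order
    return min(
        hits,
        key=lambda h: (-h.percent_identity, -h.alignment_length, h.subject_gene),
    )


def assign_counterparts(
    risk_set: RiskGeneSet,
    curated: dict[str, str],
    hits: list[HomologyHit],
    thresholds: CounterpartThresholds = CounterpartThresholds(),
    target_species: str = "target",
    query_species: str = "human",
    proxy_queries: dict[str, str] | None = None,
    case_fold: bool = True,
) -> list[CounterpartAssignment]:
    """Produce exactly one CounterpartAssignment per risk-set member.

    The curated lookup takes precedence and is never overridden by search
    evidence; when the best passing hit recovers the curated gene anyway the
    assignment carries a ``search-confirmed`` evidence flag.  ``proxy_queries``
    maps a risk gene to the paralog used as the search query in its place.
    """
    fold = (lambda s: s.casefold()) if case_fold else (lambda s: s)
    curated_by_key = {fold(k): v for k, v in curated.items()}
    proxy = {fold(k): v for k, v in (proxy_queries or {}).items()}

    primary_hits: dict[str, list[HomologyHit]] = defaultdict(list)
    other_species_hits: list[HomologyHit] = []
    for h in hits:
        if h.query_species == query_species:
            primary_hits[fold(h.query_gene)].append(h)
        else:
            other_species_hits.append(h)

    assignments: list[CounterpartAssignment] = []
    for gene in risk_set.members:
        key = fold(gene)
        query_key = key
        evidence: list[str] = []
        if key in proxy:
            query_key = fold(proxy[key])
            evidence.append(f"proxy-query:{proxy[key]}")

        gene_hits = primary_hits.get(query_key, [])
        best = _best_hit(gene_hits) if gene_hits else None
        hit_status = (
            classify_hit(best, other_species_hits, thresholds)
            if best is not None
            else STATUS_NONE
        )

        if key in curated_by_key:
            counterpart = curated_by_key[key]
            evidence.append("curated-lookup")
            if (
                best is not None
                and hit_status != STATUS_NONE
                and fold(best.subject_gene) == fold(counterpart)
            ):
                evidence.append("search-confirmed")
            assignments.append(
                CounterpartAssignment(
                    human_gene=gene,
                    target_species=target_species,
                    counterpart_gene=counterpart,
                    status=STATUS_CURATED,
                    evidence=evidence,
                )
            )
            continue

        if hit_status == STATUS_NONE:
            assignments.append(
                CounterpartAssignment(
                    human_gene=gene,
                    target_species=target_species,
                    counterpart_gene=None,
                    status=STATUS_NONE,
                    evidence=evidence,
                )
            )
            continue

        assert best is not None
        evidence.append(
            f"hit:{best.subject_gene}:identity={best.percent_identity:g}"
            f":aln={best.alignment_length}"
        )
        if hit_status == STATUS_DISTANT:
            convergent = sorted(
                {
                    h.query_species
                    for h in other_species_hits
                    if h.subject_gene == best.subject_gene
                    and h.query_species != best.query_species
                }
            )
            evidence.append("convergent:" + ",".join(convergent))
        assignments.append(
            CounterpartAssignment(
                human_gene=gene,
                target_species=target_species,
                counterpart_gene=best.subject_gene,
                status=hit_status,
                evidence=evidence,
            )
        )
    return assignments


def tally_conservation(assignments: list[CounterpartAssignment]) -> ConservationTally:
    """Fraction of genes with any counterpart; distant homologs count."""
    if not assignments:
        raise ValueError("cannot tally an empty assignment list")
    k = sum(1 for a in assignments if a.has_counterpart)
    return ConservationTally(with_counterpart=k, total=len(assignments))


def read_homology_hits(path) -> list[HomologyHit]:
    """Read a tabular hit file (TSV with header) into HomologyHit records."""
    import csv
    from pathlib import Path

    required = {
        "query_gene",
        "query_species",
        "subject_gene",
        "percent_identity",
        "alignment_length",
        "query_length",
        "subject_length",
    }
    hits: list[HomologyHit] = []
    with open(Path(path), "rt", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: hit table lacks columns {sorted(missing)}")
        for row in reader:
            hits.append(
                HomologyHit(
                    query_gene=row["query_gene"],
                    query_species=row["query_species"],
                    subject_gene=row["subject_gene"],
                    percent_identity=float(row["percent_identity"]),
                    alignment_length=int(row["alignment_length"]),
                    query_length=int(row["query_length"]),
                    subject_length=int(row["subject_length"]),
                )
            )
    return hits
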