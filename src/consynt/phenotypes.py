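"""Phenotype term normalization, category flags, and stage binning.

The model organism's phenotype strings (WormBase-style free text such as
"embryonic lethal", "extended life span") are matched by normalized substring
against an editable keyword vocabulary.  A gene is *essential* when variation
produces lethality and/or sterility; genes are also binned by the earliest
developmental stage their phenotypes touch: early (sterile, embryonic),
middle (non-embryonic development), late (locomotion, neurotransmitter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .io import PhenotypeAnnotation

logger = logging.getLogger(__name__)

STAGE_ORDER = ("early", "middle", "late")
FLAG_CATEGORIES = ("lethal", "sterile", "lifespan")


@dataclass
class PhenotypeVocabulary:
    """Keyword lists for flags, stage bins, and extra descriptive categories."""

    flags: dict[str, list[str]] = field(default_factory=dict)
    stages: dict[str, list[str]] = field(default_factory=dict)
    extra: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in (self.flags, self.stages, self.extra):
            for cat, kws in group.items():
                group[cat] = [k.strip().lower() for k in kws]

    @classmethod
    def default(cls) -> "PhenotypeVocabulary":
        text = (
            resources.files("consynt").joinpath("data/phenotype_vocabulary.yaml")
        ).read_text(encoding="utf-8")
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhenotypeVocabulary":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _normalize(term: str) -> str:
    return " ".join(term.lower().split())


def _matches(term: str, keywords: Iterable[str]) -> bool:
    return any(kw in term for kw in keywords)


def derive_flags(
    annotation: PhenotypeAnnotation,
    vocabulary: PhenotypeVocabulary | None = None,
) -> PhenotypeAnnotation:
    """Fill lethal/sterile/lifespan flags and the stage bin from raw terms.

    Returns a new annotation; unknown terms are retained unmatched.  Flags are
    invariant to term order and duplication (pure any-match semantics).
    """
    vocab = vocabulary or PhenotypeVocabulary.default()
    terms = [_normalize(t) for t in annotation.terms]
    ann = PhenotypeAnnotation(
        gene_id=annotation.gene_id,
        terms=list(annotation.terms),
        lethal=any(_matches(t, vocab.flags.get("lethal", ())) for t in terms),
        sterile=any(_matches(t, vocab.flags.get("sterile", ())) for t in terms),
        lifespan_affected=any(
            _matches(t, vocab.flags.get("lifespan", ())) for t in terms
        ),
    )
    ann.stage_category = stage_category(ann, vocab)
    return ann


def stage_category(
    annotation: PhenotypeAnnotation,
    vocabulary: PhenotypeVocabulary | None = None,
    report_all: bool = False,
) -> str | list[str]:
    """Bin a gene by developmental stage of its phenotype terms.

    ``early`` outranks ``middle`` outranks ``late`` when several apply (the
    earliest stage is reported; ``report_all`` returns every matching stage).
    A term matching an early keyword is claimed by early even if it also
    contains a middle keyword ("embryonic development" is an early phenotype).
    Non-empty term lists matching no stage keyword are ``other``; empty lists
    are ``none``.
    """
    vocab = vocabulary or PhenotypeVocabulary.default()
    terms = [_normalize(t) for t in annotation.terms]
    if not terms:
        return ["none"] if report_all else "none"
    matched = [
        stage
        for stage in STAGE_ORDER
        if any(_matches(t, vocab.stages.get(stage, ())) for t in terms)
    ]
    if not matched:
        return ["other"] if report_all else "other"
    return matched if report_all else matched[0]


@dataclass(frozen=True)
class CategoryCount:
    category: str
    k: int
    n: int

    @property
    def fraction(self) -> float:
        return self.k / self.n


def tally_categories(
    annotations: Sequence[PhenotypeAnnotation],
    genes: Iterable[str] | None = None,
    extra: bool = False,
    vocabulary: PhenotypeVocabulary | None = None,
) -> dict[str, CategoryCount]:
    """Count essential/lethal/sterile/lifespan (and optionally extra
    categories) over a gene subset.

    ``genes`` restricts to a subset of annotated gene ids; the denominator is
    the subset size.  Annotations are re-derived against the vocabulary so
    raw (flag-free) annotations are accepted.
    """
    vocab = vocabulary or PhenotypeVocabulary.default()
    by_gene = {a.gene_id: a for a in annotations}
    if genes is None:
        subset = list(by_gene)
    else:
        subset = [g for g in genes]
        unknown = [g for g in subset if g not in by_gene]
        if unknown:
            raise ValueError(
                f"{len(unknown)} genes not in the annotated universe "
                f"(first: {unknown[0]!r})"
            )
    if not subset:
        raise ValueError("cannot tally categories over an empty gene subset")

    derived = [derive_flags(by_gene[g], vocab) for g in subset]
    n = len(subset)
    counts: dict[str, CategoryCount] = {
        "essential": CategoryCount("essential", sum(a.essential for a in derived), n),
        "lethal": CategoryCount("lethal", sum(a.lethal for a in derived), n),
        "sterile": CategoryCount("sterile", sum(a.sterile for a in derived), n),
        "lifespan": CategoryCount(
            "lifespan", sum(a.lifespan_affected for a in derived), n
        ),
    }
    for stage in (*STAGE_ORDER, "other", "none"):
        counts[f"stage_{stage}"] = CategoryCount(
            f"stage_{stage}", sum(a.stage_category == stage for a in derived), n
        )
    if extra:
        for cat, kws in vocab.extra.items():
            k = sum(
                any(_matches(_normalize(t), kws) for t in a.terms) for a in derived
            )
            counts[cat] = CategoryCount(cat, k, n)
    return counts
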