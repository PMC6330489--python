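"""Most-specific shared GO terms: detection, pruning, scoring, ranking.

The pipeline takes one gene list ("within" mode) or two ("between"
mode) and

1. finds every GO term shared — after optional annotation propagation —
   by at least ``threshold`` input genes (in "between" mode at least one
   sharer must come from each list),
2. prunes every shared term that has a more specific shared descendant,
   leaving the leaves of the subgraph induced by the shared set (an
   antichain), and
3. scores each survivor by its specificity::

       score(t) = -log2(p(t)),    p(t) = 2 / g(t)

   where ``g(t)`` is the number of background genes annotated to ``t``
   and the constant 2 is the minimum background a shared term can have.
   Equivalently ``score(t) = log2(g(t)) - 1``: zero for a term shared
   only by its two background genes, growing with the term's breadth, so
   lower scores mean more specific terms.

No expression data, p-values, or fold changes are involved: the method
is deliberately a structural traversal of the ontology, not an
enrichment test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import AbstractSet, Mapping, Sequence

from .annotations import ALL, AnnotationIndex, background_count
from .errors import InputError, ScoreDomainError
from .ontology import DEFAULT_RELATIONS, OntologyDAG

#: Namespace -> Table-style category abbreviation.
CATEGORY_ABBREV = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

MIN_THRESHOLD = 2
MIN_BACKGROUND = 2


@dataclass(frozen=True)
class TrapConfig:
    """Configuration for one run.

    ``threshold`` is the minimum number of input genes that must share a
    term (minimum 2); raising it climbs the hierarchy toward broader
    terms, lowering it descends toward specific ones.  ``min_background``
    is the numerator constant of ``p(t)`` and stays at 2 unless
    explicitly overridden for sensitivity analysis.
    """

    mode: str = "within"
    threshold: int = MIN_THRESHOLD
    min_background: int = MIN_BACKGROUND
    evidence_filter: object = ALL
    relations: frozenset[str] = DEFAULT_RELATIONS
    propagate: bool = True
    namespace: str | None = None  # BP | MF | CC | None (= all)

    def __post_init__(self) -> None:
        if self.mode not in ("within", "between"):
            raise InputError(f"mode must be 'within' or 'between', got {self.mode!r}")
        if self.threshold < MIN_THRESHOLD:
            raise InputError(
                f"threshold must be at least {MIN_THRESHOLD} "
                f"(a term must be shared by at least two input genes), "
                f"got {self.threshold}"
            )
        if self.namespace is not None and self.namespace not in CATEGORY_ABBREV.values():
            raise InputError(f"namespace must be one of BP/MF/CC, got {self.namespace!r}")


@dataclass(frozen=True)
class TrappedTerm:
    """One output row: a most-specific shared term with its score."""

    term_id: str
    category: str  # BP | MF | CC
    background_genes: int
    shared_genes: tuple[str, ...]  # sorted display symbols of the sharers
    score: float
    term_name: str


def shared_terms_within(
    index: AnnotationIndex,
    genes: AbstractSet[str],
    threshold: int,
) -> dict[str, set[str]]:
    """Terms annotated to at least ``threshold`` genes of one input list.

    Returns every term ``t`` with ``|term_to_genes[t] & genes| >=
    threshold``, mapped to that intersection.
    """
    if threshold < MIN_THRESHOLD:
        raise InputError(f"threshold must be >= {MIN_THRESHOLD}, got {threshold}")
    if len(genes) < threshold:
        raise InputError(
            f"only {len(genes)} mapped input gene(s); no term can be shared "
            f"by {threshold}"
        )
    shared: dict[str, set[str]] = {}
    for term, annotated in index.term_to_genes.items():
        hit = annotated & genes
        if len(hit) >= threshold:
            shared[term] = hit
    return shared


def shared_terms_between(
    index: AnnotationIndex,
    list_a: AbstractSet[str],
    list_b: AbstractSet[str],
    threshold: int,
) -> dict[str, set[str]]:
    """Terms shared across two lists, with at least one sharer from each.

    A term qualifies when its annotated genes intersect both lists and
    the combined intersection has at least ``threshold`` genes.  A gene
    present in both lists is counted once and satisfies both sides; a
    warning is emitted because such overlap blurs the two-list contrast.
    """
    if threshold < MIN_THRESHOLD:
        raise InputError(f"threshold must be >= {MIN_THRESHOLD}, got {threshold}")
    overlap = set(list_a) & set(list_b)
    if overlap:
        warnings.warn(
            f"{len(overlap)} gene(s) appear in both input lists and are "
            f"counted once: {', '.join(sorted(overlap))}",
            stacklevel=2,
        )
    union = set(list_a) | set(list_b)
    shared: dict[str, set[str]] = {}
    for term, annotated in index.term_to_genes.items():
        hit = annotated & union
        if len(hit) >= threshold and hit & list_a and hit & list_b:
            shared[term] = hit
    return shared


def prune_shared_parents(
    dag: OntologyDAG,
    shared: Mapping[str, AbstractSet[str]],
) -> dict[str, set[str]]:
    """Keep only shared terms with no more specific shared descendant.

    A shared term is removed exactly when one of its strict descendants
    (under the configured relations) is also shared; what remains are
    the leaves of the subgraph induced by the shared set.  Gene sets of
    the survivors are unchanged.  Note the test is descendant-in-shared-
    set, not child-in-full-ontology: a term may well have children in
    the full ontology and still be the most specific *shared* term.
    """
    keys = set(shared)
    return {
        term: set(genes)
        for term, genes in shared.items()
        if not (dag.descendants(term) & keys)
    }


def score_term(g: int, min_background: int = MIN_BACKGROUND) -> float:
    """Specificity score ``-log2(min_background / g) = log2(g) - log2(min_background)``.

    Strictly increasing in ``g`` and zero at ``g == min_background``;
    fewer background genes mean a lower score and a more specific term.

    Raises
    ------
    ScoreDomainError
        If ``g < min_background`` (p(t) would exceed 1).
    """
    if g < min_background:
        raise ScoreDomainError(
            f"background count {g} below minimum {min_background}: "
            f"p(t) would exceed 1"
        )
    return math.log2(g) - math.log2(min_background)


def rank(terms: Sequence[TrappedTerm]) -> list[TrappedTerm]:
    """Stable sort ascending by score; ties broken by GO id."""
    return sorted(terms, key=lambda t: (t.score, t.term_id))


def run(
    config: TrapConfig,
    dag: OntologyDAG,
    index: AnnotationIndex,
    genes: AbstractSet[str],
    genes_b: AbstractSet[str] | None = None,
) -> list[TrappedTerm]:
    """Full pipeline: shared -> prune -> score -> rank.

    ``genes`` (and ``genes_b`` in "between" mode) are mapped gene ids,
    e.g. the matched set from :func:`goshare.annotations.map_genes`.
    """
    terms, _ = run_with_stats(config, dag, index, genes, genes_b)
    return terms


def run_with_stats(
    config: TrapConfig,
    dag: OntologyDAG,
    index: AnnotationIndex,
    genes: AbstractSet[str],
    genes_b: AbstractSet[str] | None = None,
) -> tuple[list[TrappedTerm], dict[str, int]]:
    """Like :func:`run` but also returns pre/post-pruning term counts."""
    if config.mode == "within":
        shared = shared_terms_within(index, genes, config.threshold)
    else:
        if genes_b is None:
            raise InputError("between mode requires a second gene list")
        shared = shared_terms_between(index, genes, genes_b, config.threshold)

    pruned = prune_shared_parents(dag, shared)

    rows: list[TrappedTerm] = []
    for term, sharers in pruned.items():
        meta = dag.terms[term]
        category = CATEGORY_ABBREV.get(meta.namespace, meta.namespace)
        if config.namespace is not None and category != config.namespace:
            continue
        g = background_count(index, term)
        rows.append(
            TrappedTerm(
                term_id=term,
                category=category,
                background_genes=g,
                shared_genes=tuple(sorted(index.symbol_of(s) for s in sharers)),
                score=score_term(g, config.min_background),
                term_name=meta.name,
            )
        )
    stats = {"terms_shared": len(shared), "terms_retained": len(pruned)}
    return rank(rows), stats
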