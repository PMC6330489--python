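"""GAF annotation ingestion, evidence filtering, and background counts.

Reads GAF 2.1/2.2 gene-association files, filters records by evidence
code, drops NOT-qualified annotations, and builds a bidirectional
gene <-> term index.  By default annotations are propagated up the
ontology (the true-path rule: a gene annotated to a term is implicitly
annotated to every ancestor of that term), which is the convention
behind background counts such as the Bioconductor ``GO2ALLEGS`` maps.
``g(t)``, the number of background genes annotated to term ``t``, is
always counted over the whole filtered annotation source, never over
the input gene lists.

Genes are keyed internally by their database object id (GAF column 2);
symbols (column 3) are a case-insensitive matching convenience, because
symbols collide across sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

from .errors import GafParseError, InputError, ObsoleteTermError, UnknownTermError
from .ontology import OntologyDAG

#: Closed GO evidence-code vocabulary (experimental, high-throughput,
#: phylogenetic, computational, author/curator statements, electronic).
EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "IBA", "IBD", "IKR", "IRD",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA",
    }
)

#: Sentinel meaning "keep every evidence code".
ALL = "ALL"

_GAF_COLUMNS = 17


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF line: a gene-to-term assignment with provenance."""

    gene_id: str
    gene_symbol: str
    qualifier: tuple[str, ...]
    term_id: str
    evidence_code: str
    taxon: str = ""


@dataclass
class AnnotationIndex:
    """Bidirectional gene <-> term maps after filtering and propagation.

    ``gene_to_terms`` and ``term_to_genes`` are exact transposes.  When
    ``propagated`` is true, every gene annotated to a term is also
    recorded on all of that term's ancestors.  ``background_size`` is
    the number of distinct genes indexed.  ``quarantined`` holds the
    records whose term id could not be resolved in the companion
    ontology (unknown or obsolete); they contribute nothing to counts.
    """

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]
    propagated: bool
    background_size: int
    symbols: dict[str, str] = field(default_factory=dict)
    quarantined: list[AnnotationRecord] = field(default_factory=list)
    dag: OntologyDAG | None = field(default=None, repr=False)

    def symbol_of(self, gene_id: str) -> str:
        """Display symbol for a gene id (the id itself if none recorded)."""
        return self.symbols.get(gene_id, gene_id)


def read_gaf(
    path: str | PathLike,
    evidence_filter: str | Iterable[str] = ALL,
) -> list[AnnotationRecord]:
    """Read a GAF 2.x file, keeping records that pass the evidence filter.

    NOT-qualified records are always excluded (standard GAF negation
    semantics).  Lines starting with ``!`` are comments.

    Parameters
    ----------
    path
        Tab-separated GAF 2.1/2.2 file with 17 columns.
    evidence_filter
        ``"ALL"`` or a set of evidence codes to retain.

    Raises
    ------
    GafParseError
        On a non-comment line with the wrong column count or an evidence
        code outside the GO vocabulary; the message gives the line number.
    """
    if evidence_filter != ALL:
        evidence_filter = frozenset(evidence_filter)
        bad = evidence_filter - EVIDENCE_CODES
        if bad:
            raise ValueError(f"unknown evidence codes in filter: {sorted(bad)}")

    records: list[AnnotationRecord] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != _GAF_COLUMNS:
                raise GafParseError(
                    f"line {lineno}: expected {_GAF_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            qualifier = tuple(q for q in fields[3].split("|") if q)
            evidence = fields[6]
            if evidence not in EVIDENCE_CODES:
                raise GafParseError(
                    f"line {lineno}: unknown evidence code {evidence!r}"
                )
            if "NOT" in qualifier:
                continue
            if evidence_filter != ALL and evidence not in evidence_filter:
                continue
            records.append(
                AnnotationRecord(
                    gene_id=fields[1],
                    gene_symbol=fields[2],
                    qualifier=qualifier,
                    term_id=fields[4],
                    evidence_code=evidence,
                    taxon=fields[12],
                )
            )
    return records


def build_index(
    records: Sequence[AnnotationRecord],
    dag: OntologyDAG,
    propagate: bool = True,
) -> AnnotationIndex:
    """Build the gene <-> term index from filtered records.

    Records whose term id does not resolve (unknown, or obsolete) are
    quarantined, not dropped silently.  Duplicate (gene, term) pairs
    collapse.  With ``propagate`` every pair is extended to all
    ancestors of the annotated term.
    """
    gene_to_terms: dict[str, set[str]] = {}
    symbols: dict[str, str] = {}
    quarantined: list[AnnotationRecord] = []

    for record in records:
        try:
            term = dag.resolve(record.term_id)
        except (UnknownTermError, ObsoleteTermError):
            quarantined.append(record)
            continue
        terms = gene_to_terms.setdefault(record.gene_id, set())
        terms.add(term)
        if propagate:
            terms.update(dag.ancestors(term))
        symbols.setdefault(record.gene_id, record.gene_symbol)

    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        for term in terms:
            term_to_genes.setdefault(term, set()).add(gene)

    return AnnotationIndex(
        gene_to_terms=gene_to_terms,
        term_to_genes=term_to_genes,
        propagated=propagate,
        background_size=len(gene_to_terms),
        symbols=symbols,
        quarantined=quarantined,
        dag=dag,
    )


def map_genes(
    index: AnnotationIndex,
    raw_list: Sequence[str],
) -> tuple[set[str], list[str]]:
    """Match raw identifiers against the index, case-insensitively.

    Each entry is matched first against gene symbols, then against gene
    ids.  Duplicates collapse.  Unmatched entries come back verbatim for
    reporting; they are never silently dropped.

    Raises
    ------
    InputError
        If the list is empty after stripping blanks.
    """
    entries = [e.strip() for e in raw_list]
    entries = [e for e in entries if e and not e.startswith("#")]
    if not entries:
        raise InputError("gene list is empty after stripping blank lines")

    by_symbol: dict[str, str] = {}
    for gene_id, symbol in index.symbols.items():
        by_symbol.setdefault(symbol.casefold(), gene_id)
    by_id = {gene_id.casefold(): gene_id for gene_id in index.gene_to_terms}

    matched: set[str] = set()
    unmatched: list[str] = []
    seen_unmatched: set[str] = set()
    for entry in entries:
        key = entry.casefold()
        if key in by_symbol:
            matched.add(by_symbol[key])
        elif key in by_id:
            matched.add(by_id[key])
        elif key not in seen_unmatched:
            seen_unmatched.add(key)
            unmatched.append(entry)
    return matched, unmatched


def background_count(index: AnnotationIndex, term_id: str) -> int:
    """``g(t)``: number of distinct background genes annotated to a term.

    Zero for a resolvable term with no annotations.  Resolution errors
    propagate for unknown/obsolete ids.
    """
    if index.dag is not None:
        term_id = index.dag.resolve(term_id)
    return len(index.term_to_genes.get(term_id, ()))


def read_gene_list(path: str | PathLike) -> list[str]:
    """Read a plain-text gene list: one identifier per line, ``#`` comments."""
    with open(path, encoding="utf-8") as handle:
        return [
            line.strip()
            for line in handle
            if line.strip() and not line.lstrip().startswith("#")
        ]
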