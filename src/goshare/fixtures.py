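"""Seeded synthetic OBO + GAF + gene-list fixtures with planted ground truth.

The generator emulates the structures the pipeline must handle — a
multi-rooted three-namespace DAG with multi-parent terms and depth of
at least four, direct gene annotations with mixed evidence codes, a
NOT-qualified record, an alt_id, an obsolete term, and two gene lists
with a planted overlap and a planted shared leaf — without any network
download.  Regenerating with the same seed reproduces identical files
byte for byte.

:func:`oracle` is an independent brute-force implementation of the
whole shared-term pipeline.  It reads only the manifest (never the
files, never the library's index structures) and computes its own
ancestor/descendant closures by iterated single-step expansion, so it
is a genuine cross-check of the trapper pipeline rather than a second
call into it.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FixtureError

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
_ABBREV = {"biological_process": "BP", "molecular_function": "MF", "cellular_component": "CC"}

#: Evidence-code mix drawn for random annotations (code -> weight).
DEFAULT_EVIDENCE_MIX: dict[str, float] = {
    "IDA": 0.35, "IEA": 0.30, "IMP": 0.15, "TAS": 0.12, "ND": 0.08,
}


@dataclass
class FixtureManifest:
    """Everything needed to regenerate and to independently verify a fixture.

    ``expected`` holds oracle outputs (computed by :func:`oracle`, never
    by the trapper pipeline) for both modes at a few thresholds.
    """

    seed: int
    n_terms_per_namespace: int
    terms: list[dict]  # {id, name, namespace}
    edges: list[list[str]]  # [child, relation, parent]
    alt_ids: dict[str, str]  # alt -> primary
    obsolete: list[str]
    annotations: list[dict]  # {gene_id, symbol, term, evidence, qualifier}
    list_a: list[str]  # symbols
    list_b: list[str]
    planted: dict = field(default_factory=dict)  # e.g. shared_leaf, sharers
    files: dict[str, str] = field(default_factory=dict)
    expected_term_to_genes: dict[str, list[str]] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def save(self, path: str | PathLike) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | PathLike) -> "FixtureManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _go_id(counter: int) -> str:
    return f"GO:{counter:07d}"


def generate(
    seed: int,
    out_dir: str | PathLike,
    n_terms: int = 12,
    n_genes: int = 30,
    p_multi_parent: float = 0.3,
    evidence_mix: Mapping[str, float] | None = None,
    plant_quarantined: bool = False,
) -> FixtureManifest:
    """Write a synthetic OBO, GAF 2.2, and two gene lists under ``out_dir``.

    Parameters
    ----------
    seed
        Drives every random choice; equal seeds give identical bytes.
    n_terms
        Terms per namespace (>= 3).  The first five terms of each
        namespace form a chain, guaranteeing depth >= 4; later terms
        attach to random earlier terms (acyclicity by construction:
        edges only point from later terms to earlier ones in the
        generation order).
    n_genes
        Number of annotated background genes (>= 2).
    p_multi_parent
        Probability that a non-chain term receives a second parent.
    evidence_mix
        Weights for drawing evidence codes; default
        :data:`DEFAULT_EVIDENCE_MIX`.
    plant_quarantined
        Also annotate the obsolete term, so exactly one record must be
        quarantined downstream.
    """
    if n_terms < 3:
        raise FixtureError(f"need at least 3 terms per namespace, got {n_terms}")
    if n_genes < 2:
        raise FixtureError(f"need at least 2 genes, got {n_genes}")
    mix = dict(evidence_mix or DEFAULT_EVIDENCE_MIX)
    rng = random.Random(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    terms: list[dict] = []
    edges: list[list[str]] = []
    counter = 0
    per_ns: dict[str, list[str]] = {}
    chain_depth = min(5, n_terms)
    for ns in NAMESPACES:
        ids: list[str] = []
        for i in range(n_terms):
            counter += 1
            tid = _go_id(counter)
            ids.append(tid)
            terms.append({"id": tid, "name": f"{_ABBREV[ns]} term {i}", "namespace": ns})
            if i == 0:
                continue
            if i < chain_depth:
                parents = [i - 1]  # spine guaranteeing depth >= 4
            else:
                parents = [rng.randrange(i)]
                if rng.random() < p_multi_parent:
                    extra = rng.randrange(i)
                    if extra not in parents:
                        parents.append(extra)
            for p in parents:
                relation = "is_a" if rng.random() < 0.8 else "part_of"
                edges.append([tid, relation, ids[p]])
        per_ns[ns] = ids

    # planted alt_id on a random non-root BP term, and one obsolete term
    alt_target = rng.choice(per_ns["biological_process"][1:])
    alt_ids = {_go_id(9000000 + seed % 1000): alt_target}
    counter += 1
    obsolete_id = _go_id(counter)
    obsolete = [obsolete_id]

    genes = [(f"FIX:{i:04d}", f"GENE{i:03d}") for i in range(1, n_genes + 1)]
    codes = sorted(mix)
    weights = [mix[c] for c in codes]
    annotatable = [t["id"] for t in terms if t["id"] not in {per_ns[ns][0] for ns in NAMESPACES}]

    annotations: list[dict] = []
    for gene_id, symbol in genes:
        for term in rng.sample(annotatable, k=rng.randint(1, 4)):
            annotations.append(
                {
                    "gene_id": gene_id,
                    "symbol": symbol,
                    "term": term,
                    "evidence": rng.choices(codes, weights=weights, k=1)[0],
                    "qualifier": "involved_in",
                }
            )

    # planted shared leaf: the two first genes on the deepest BP chain term,
    # reproducing the two-genes-share-child-and-parent scenario end to end
    leaf = per_ns["biological_process"][chain_depth - 1]
    for gene_id, symbol in genes[:2]:
        annotations.append(
            {"gene_id": gene_id, "symbol": symbol, "term": leaf,
             "evidence": "IDA", "qualifier": "involved_in"}
        )
    # planted NOT-qualified record (must be excluded by the reader)
    gene_id, symbol = genes[2 % n_genes]
    annotations.append(
        {"gene_id": gene_id, "symbol": symbol, "term": leaf,
         "evidence": "IDA", "qualifier": "NOT|involved_in"}
    )
    # one record through the alt_id, exercising secondary-accession resolution
    gene_id, symbol = genes[1]
    annotations.append(
        {"gene_id": gene_id, "symbol": symbol, "term": next(iter(alt_ids)),
         "evidence": "TAS", "qualifier": "involved_in"}
    )
    if plant_quarantined:
        gene_id, symbol = genes[0]
        annotations.append(
            {"gene_id": gene_id, "symbol": symbol, "term": obsolete_id,
             "evidence": "IEA", "qualifier": "involved_in"}
        )

    # deduplicate (gene, term, qualifier) keeping first evidence, stable order
    seen: set[tuple[str, str, str]] = set()
    unique_annotations = []
    for rec in annotations:
        key = (rec["gene_id"], rec["term"], rec["qualifier"])
        if key not in seen:
            seen.add(key)
            unique_annotations.append(rec)
    annotations = unique_annotations

    # gene lists by symbol: list A gets the planted sharers; one overlap gene
    size_a = min(10, n_genes)
    size_b = min(12, n_genes)
    list_a = [s for _, s in genes[:size_a]]
    b_start = min(size_a, max(0, n_genes - size_b))
    list_b = [s for _, s in genes[b_start : b_start + size_b]]
    if list_a and list_a[0] not in list_b:
        list_b[-1] = list_a[0]  # planted overlap pattern

    manifest = FixtureManifest(
        seed=seed,
        n_terms_per_namespace=n_terms,
        terms=terms,
        edges=edges,
        alt_ids=alt_ids,
        obsolete=obsolete,
        annotations=annotations,
        list_a=list_a,
        list_b=sorted(set(list_b)),
        planted={"shared_leaf": leaf, "sharers": [s for _, s in genes[:2]]},
    )
    manifest.expected_term_to_genes = {
        t: sorted(g)
        for t, g in _oracle_term_to_genes(manifest).items()
    }
    for mode in ("within", "between"):
        manifest.expected[mode] = {
            str(thr): [
                [row[0], row[1], row[2], list(row[3]), row[4]]
                for row in oracle(manifest, mode, thr)
            ]
            for thr in (2, 3, 4)
        }

    files = {
        "obo": str(out / "fixture.obo"),
        "gaf": str(out / "fixture.gaf"),
        "list_a": str(out / "genes_a.txt"),
        "list_b": str(out / "genes_b.txt"),
        "manifest": str(out / "manifest.json"),
    }
    _write_obo(files["obo"], manifest)
    _write_gaf(files["gaf"], manifest)
    Path(files["list_a"]).write_text("\n".join(manifest.list_a) + "\n", encoding="utf-8")
    Path(files["list_b"]).write_text("\n".join(manifest.list_b) + "\n", encoding="utf-8")
    manifest.files = files
    manifest.save(files["manifest"])
    return manifest


def _write_obo(path: str, manifest: FixtureManifest) -> None:
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, relation, parent in manifest.edges:
        parents.setdefault(child, []).append((relation, parent))
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in manifest.alt_ids.items():
        alt_by_primary.setdefault(primary, []).append(alt)

    lines = ["format-version: 1.2", f"ontology: goshare-fixture-{manifest.seed}", ""]
    for term in manifest.terms:
        lines += [
            "[Term]",
            f"id: {term['id']}",
            f"name: {term['name']}",
            f"namespace: {term['namespace']}",
        ]
        for alt in sorted(alt_by_primary.get(term["id"], [])):
            lines.append(f"alt_id: {alt}")
        for relation, parent in sorted(parents.get(term["id"], [])):
            if relation == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {relation} {parent}")
        lines.append("")
    for tid in manifest.obsolete:
        lines += [
            "[Term]",
            f"id: {tid}",
            "name: obsolete fixture term",
            "namespace: biological_process",
            "is_obsolete: true",
            "",
        ]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def _write_gaf(path: str, manifest: FixtureManifest) -> None:
    aspect = {t["id"]: _ASPECT[t["namespace"]] for t in manifest.terms}
    lines = ["!gaf-version: 2.2"]
    for rec in manifest.annotations:
        lines.append(
            "\t".join(
                (
                    "FIXDB",
                    rec["gene_id"],
                    rec["symbol"],
                    rec["qualifier"],
                    rec["term"],
                    "FIXDB:REF:0000001",
                    rec["evidence"],
                    "",
                    aspect.get(rec["term"], "P"),
                    "",
                    "",
                    "protein",
                    "taxon:9606",
                    "20180101",
                    "FIXDB",
                    "",
                    "",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Independent brute-force oracle.  Deliberately shares no code with the
# ontology/annotations/trapper modules: closures by iterated one-step
# expansion, scoring via natural logs.
# ---------------------------------------------------------------------------


def _oracle_parent_map(
    manifest: FixtureManifest,
    relations: Iterable[str] = ("is_a", "part_of"),
) -> dict[str, set[str]]:
    allowed = set(relations)
    parent_map: dict[str, set[str]] = {}
    for child, relation, parent in manifest.edges:
        if relation in allowed:
            parent_map.setdefault(child, set()).add(parent)
    return parent_map


def _expand_to_fixpoint(start: str, step: Mapping[str, set[str]]) -> set[str]:
    """All nodes reachable from ``start`` by iterating ``step``, excluding it."""
    closure: set[str] = set()
    frontier = set(step.get(start, ()))
    while frontier:
        closure |= frontier
        frontier = {
            nxt for node in frontier for nxt in step.get(node, ()) if nxt not in closure
        }
    return closure


def _oracle_term_to_genes(
    manifest: FixtureManifest,
    evidence_filter: Iterable[str] | str = "ALL",
    relations: Iterable[str] = ("is_a", "part_of"),
    propagate: bool = True,
) -> dict[str, set[str]]:
    parent_map = _oracle_parent_map(manifest, relations)
    obsolete = set(manifest.obsolete)
    term_to_genes: dict[str, set[str]] = {}
    keep_codes = None if evidence_filter == "ALL" else set(evidence_filter)
    for rec in manifest.annotations:
        if "NOT" in rec["qualifier"].split("|"):
            continue
        if keep_codes is not None and rec["evidence"] not in keep_codes:
            continue
        term = manifest.alt_ids.get(rec["term"], rec["term"])
        if term in obsolete:
            continue
        hit_terms = {term}
        if propagate:
            hit_terms |= _expand_to_fixpoint(term, parent_map)
        for t in hit_terms:
            term_to_genes.setdefault(t, set()).add(rec["symbol"])
    return term_to_genes


def oracle(
    manifest: FixtureManifest,
    mode: str,
    threshold: int,
    evidence_filter: Iterable[str] | str = "ALL",
    relations: Iterable[str] = ("is_a", "part_of"),
    propagate: bool = True,
) -> list[tuple]:
    """Exhaustive reference pipeline over the manifest.

    Enumerates every term, intersects its (propagated) gene symbols with
    the input lists, applies the within/between sharing condition,
    deletes any qualifying term that has a strict descendant in the
    qualifying set, scores survivors with ``-log(2/g)/log(2)``, and
    sorts ascending by (score, term id).

    Returns rows ``(term_id, category, background, shared_symbols, score)``
    with ``shared_symbols`` a sorted tuple.
    """
    term_to_genes = _oracle_term_to_genes(manifest, evidence_filter, relations, propagate)
    namespace = {t["id"]: t["namespace"] for t in manifest.terms}

    fold = lambda symbols: {s.casefold() for s in symbols}  # noqa: E731
    known = {s.casefold(): s for g in term_to_genes.values() for s in g}
    set_a = {known[s] for s in fold(manifest.list_a) if s in known}
    set_b = {known[s] for s in fold(manifest.list_b) if s in known}

    qualifying: dict[str, set[str]] = {}
    for term, symbols in term_to_genes.items():
        if mode == "within":
            hit = symbols & set_a
            ok = len(hit) >= threshold
        else:
            hit = symbols & (set_a | set_b)
            ok = len(hit) >= threshold and bool(hit & set_a) and bool(hit & set_b)
        if ok:
            qualifying[term] = hit

    # strict-descendant deletion via a child map expanded to fixpoint
    child_map: dict[str, set[str]] = {}
    allowed = set(relations)
    for child, relation, parent in manifest.edges:
        if relation in allowed:
            child_map.setdefault(parent, set()).add(child)

    rows = []
    for term, hit in qualifying.items():
        if _expand_to_fixpoint(term, child_map) & qualifying.keys():
            continue
        g = len(term_to_genes[term])
        score = -(math.log(2.0 / g) / math.log(2.0))
        rows.append(
            (term, _ABBREV[namespace[term]], g, tuple(sorted(hit)), score)
        )
    rows.sort(key=lambda r: (r[4], r[0]))
    return rows


def oracle_shared_count(
    manifest: FixtureManifest,
    mode: str,
    threshold: int,
) -> int:
    """Number of qualifying terms before the strict-descendant deletion."""
    term_to_genes = _oracle_term_to_genes(manifest)
    known = {s.casefold(): s for g in term_to_genes.values() for s in g}
    set_a = {known[s.casefold()] for s in manifest.list_a if s.casefold() in known}
    set_b = {known[s.casefold()] for s in manifest.list_b if s.casefold() in known}
    count = 0
    for symbols in term_to_genes.values():
        if mode == "within":
            if len(symbols & set_a) >= threshold:
                count += 1
        else:
            hit = symbols & (set_a | set_b)
            if len(hit) >= threshold and hit & set_a and hit & set_b:
                count += 1
    return count
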