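# Methods

## Model

Let the ontology be a directed acyclic graph `G = (T, E)` whose nodes
are GO terms and whose edges are typed child→parent links. Only edge
types in the configured relation set `R` are considered; the default is
`R = {is_a, part_of}`, the conventional GO parent semantics. The
regulates family (`regulates`, `positively_regulates`,
`negatively_regulates`) is excluded by default but selectable, because
which relations belong in a term's "parents" is a modelling choice, not
a property of the data. Ancestors/descendants are transitive closures
over `R`, excluding the query term itself; cross-namespace edges (which
`part_of` can create) are followed like any other.

An annotation source assigns genes to terms. Under the **true-path
rule** a gene annotated to `t` is implicitly annotated to every
ancestor of `t`; the index propagates annotations by default, so that
the background count

> `g(t)` = number of distinct genes annotated to `t` after propagation,
> counted over the entire filtered annotation file

is ancestor-inclusive, matching the `GO2ALLEGS`-style maps of the
Bioconductor annotation packages. Propagation is switchable
(`--no-propagate`) for sensitivity analysis, since published background
counts do not always say which convention they use. `g(t)` is never
computed over the input lists: it is a property of the background.

Given input gene sets `A` (and `B` in between mode) and a threshold
`k ≥ 2`, a term `t` with propagated gene set `N(t)` **qualifies** when

- *within*: `|N(t) ∩ A| ≥ k`;
- *between*: with `S = N(t) ∩ (A ∪ B)`, require `|S| ≥ k`,
  `S ∩ A ≠ ∅`, and `S ∩ B ≠ ∅`.

A gene present in both lists is counted once and satisfies both sides
(double counting would inflate sharing); a warning is emitted. How a
threshold above 2 should distribute across the two lists is genuinely
open; only the total-plus-one-from-each rule is implemented.

**Pruning** deletes every qualifying term that has a *strict descendant
in the qualifying set*. The survivors are the leaves of the subgraph
induced by the qualifying set — an antichain, checked as an invariant.
Note the test is descendant-in-shared-set, not has-children-in-the-
full-ontology: a term may have thousands of children in GO and still be
the most specific *shared* term. With propagation on, the two readings
coincide on direct children (a shared child implies a shared parent);
the descendant form remains correct when propagation is off.

**Scoring.** Each survivor gets `score(t) = −log₂(m / g(t))` with
`m = 2`, the minimum background a shared term can have, i.e.
`score(t) = log₂ g(t) − 1 ≥ 0`, strictly increasing in `g(t)` and zero
at `g(t) = 2`. The logarithm base is fixed to 2: it is the unique base
that reproduces all ten known (g, score) reference pairs to four
decimal places (e.g. g = 27 → 3.7549, g = 66 → 5.0444), which the test
suite asserts. `m` is overridable for sensitivity analysis but is a
constant of the method, not a tuning knob. Output is sorted ascending
by score with ties broken by GO id, so identical inputs always produce
identical bytes.

## Input handling

- **OBO**: parsed with `obonet`; only `[Term]` stanzas are interpreted,
  `[Typedef]`, `intersection_of` and `disjoint_from` are ignored.
  Obsolete terms are excluded from the graph but kept in a side index
  so annotations to them are *quarantined* (counted and reportable)
  rather than dropped. `alt_id` accessions resolve to their primary
  term. Malformed stanza lines fail with the line number; a cycle under
  the chosen relations fails validation with one witness cycle;
  dangling parent references are errors.
- **GAF 2.1/2.2**: 17 tab-separated columns, `!` comments. Records with
  `NOT` in the qualifier are always excluded (standard negation
  semantics). The evidence filter defaults to all codes, since evidence
  pre-selection is an option, not a default restriction. Unknown
  evidence codes are parse errors (the vocabulary is closed).
- **Gene lists**: one identifier per line, `#` comments. Entries match
  case-insensitively against symbols first, then database ids; genes
  are keyed internally by database object id because symbols collide
  across sources. Unmatched entries are reported verbatim, never
  silently dropped. Namespaces are processed together; `--namespace`
  filters the output rows only.

## Synthetic fixtures and what passing them shows

`goshare.fixtures.generate(seed, ...)` writes a synthetic OBO, GAF 2.2,
and two gene lists with planted ground truth. Defaults: 12 terms in
each of the three namespaces (36 total), 30 annotated genes with 1–4
direct annotations each, multi-parent probability 0.3, is_a:part_of
edge mix 4:1, evidence mix dominated by IDA/IEA. Acyclicity is by
construction (edges only point from later to earlier terms in the
generation order) and a five-term spine per namespace guarantees depth
≥ 4. Planted features: one alt_id, one obsolete term, one NOT-qualified
record, one annotation through the alt_id, a pair of genes sharing a
deep term (the worked two-gene child/parent scenario), and one gene
present in both lists. Fixture sizes were chosen so that the whole
100-seed equivalence sweep stays interactive (a few seconds) while
still exercising multi-parents, diamonds, and cross-namespace sharing.

The generator emulates *structure*, not statistics: it does not
reproduce GO's term-size distribution, its ~45 000-term scale, or the
long-tailed annotation counts of real genomes. Passing the fixture
suite therefore demonstrates algorithmic correctness (sharing, pruning,
scoring, ordering, error handling) — not that any particular biological
result will be recovered from a given ontology release, which depends
entirely on the annotation snapshot used.

`goshare.fixtures.oracle` is an independent brute-force implementation
of the whole pipeline used as the cross-check: it reads only the
generator's manifest, computes closures by iterated one-step expansion
to a fixpoint, applies the sharing condition exhaustively, deletes
terms with a qualifying strict descendant, and scores with natural
logs (`−log(2/g)/log 2`). It shares no code with the library modules.
The acceptance suite asserts pipeline/oracle identity — term sets,
gene sets, scores to 1e−9, and order — over 100 seeds, both modes,
thresholds 2–6.

## Numerical and design notes

- Scores are exact floating-point `log2` expressions; the only rounding
  is presentational (four decimal places in the TSV, half-even, the
  precision the score is conventionally reported at).
- Tie-break by GO id makes ranking a total order; the gene column is
  sorted lexicographically. There is no randomness anywhere in the main
  pipeline.
- Degenerate inputs: a gene list shorter than the threshold is an input
  error (no term could qualify); a term with no annotations has
  `g(t) = 0` and can never be scored because it can never qualify;
  `g < 2` raises a domain error rather than returning a negative score.
- Thresholds below 2 are rejected: a "shared" term needs at least two
  sharers by definition.

## Known limitations

- No enrichment statistics, by design: the method is a structural
  alternative to hypergeometric/Fisher/binomial testing, not a
  replacement for it.
- No identifier mapping beyond case-insensitive symbol/id matching; no
  GPAD/GPI input; no OWL; single annotation file per run.
- Between-mode thresholds above 2 apply to the combined sharer set with
  only a one-per-list minimum; per-list minimums are not implemented.
- Published term counts obtained with specific annotation-database
  releases are version-bound and are not reproduced here; the
  pre/post-pruning counts in the run report are instead validated
  against the brute-force oracle on fixtures.
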