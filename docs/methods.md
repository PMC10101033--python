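# Methods

This document describes the models and conventions implemented by
`silico16s`, the parameters they expose, and the design choices made where a
published survey's description leaves room for interpretation.

## 1. Analysis units and sanitization (`silico16s.io`)

**Unit = chromosome.** Every sequence record of a genome is treated as an
independent complete genome ("unit", named `<genome_id>__c<i>`), so a
two-chromosome genome contributes two units to every downstream count. This
matches survey practice where replicon-level records are evaluated
separately; it also means a genome's copies can split across units.

**Ambiguity sanitization.** Ambiguous IUPAC positions are replaced by a
uniformly random member of the letter's expansion set. Replacement is seeded
and consumed in scan order; units are processed in sorted unit-id order with
per-unit derived seeds, so results are independent of input order and
machine. A unit containing a run of more than `run_threshold` (default 10)
*consecutive* ambiguous characters is excluded from all downstream analysis
and appears only in the sanitization report (conservation of records: every
unit read ends up either in the outputs or in the exclusion log).

**Taxonomy.** An eight-rank table (superkingdom … species, strain) keyed by
genome id; a missing strain label falls back to the species label. The
bacteria/archaea evaluation split is driven by the superkingdom rank.

## 2. Gene finding (`silico16s.genefinder`)

A classic k-mer-density finder:

1. Build a reference panel from known full-length genes: the set of all
   13-mers (closed under reverse complement) plus terminal anchor motifs
   (first and last 15 nt of each panel gene).
2. Scan each unit in 100-nt windows (step = window/2): windows whose
   fraction of panel k-mers ≥ 0.30 are marked; adjacent marked windows
   merge into candidate segments when the gap is < one window. Candidate
   strand is the majority orientation of matched k-mers.
3. Anchor each candidate: pad it by one maximum gene length on each side
   (density dips can split one gene across candidates; the pad guarantees
   both terminal motifs are reachable), orient the region by candidate
   strand, and pair every start motif with an end motif giving a gene length
   in [1,200, 1,900] nt, breaking ties toward the panel's median length.
   Duplicate anchors from split or overlapping candidates collapse by
   coordinate-overlap deduplication.

Extracted genes are always reported in sense orientation with 0-based
half-open unit coordinates. Parameters k = 13, window = 100, density = 0.30,
and the length range are configuration (exposed via `RunConfig`), not claims:
the source survey names the algorithm family but none of its constants.

**Bypass.** A pre-extracted gene FASTA (`<unit_id>|gene<i>`, sense
orientation) can replace the finder, so downstream metrics never depend on
the finder's heuristics. On synthetic data with divergence 0 the two paths
produce byte-identical reports (tested).

## 3. Redundancy statistics (`silico16s.redundancy`)

- **Copy number** = genes per unit; **variant** = distinct exact gene
  sequence within a unit (a single substitution or length difference makes a
  new variant).
- **Aggregation** is hierarchical mean-of-means: per-unit values are averaged
  within species; each higher rank averages the means of its immediate child
  taxa. The strain rank instead reports raw (max, min) counts.
- **Copy-number spectra** band species means — bacteria: 1, 2–6, ≥7;
  archaea: 1, 2–3, >3; a mean m is in band (lo, hi] iff lo < m ≤ hi. Band
  edges are configuration. The headline "more than one copy" percentage uses
  the total species count as denominator.

## 4. In silico PCR (`silico16s.pcr`)

**Matching policy.** A degenerate primer matches a target substring exactly
when every target base is a member of the corresponding IUPAC expansion set —
zero mismatches, no gaps, no melting-temperature model. The forward primer is
searched as written on the extracted gene (sense strand); the reverse primer
via its IUPAC reverse complement. The amplicon spans from the first base of
the *leftmost* forward match to the last base of the *rightmost* reverse
match ending after the forward start (the maximal fragment, primers
included). A gene yields at most one amplicon per pair, so per-unit amplicon
counts never exceed gene counts.

**Span-length conventions.** The bundled primer table stores each pair's
printed reference positions. The table's printed span equals reverse-last −
forward-first, one less than the inclusive base count; both are exposed
(`paper_span_length`, `inclusive_span_length`). Mean amplicon lengths are
categorized S [100, 300], M (300, 600], L > 600, "undersized" below 100.

## 5. MA detection and primer metrics (`silico16s.metrics`)

- **MA group**: amplicons of one pair grouped by exact sequence identity,
  keeping groups that span ≥ 2 distinct *species* (identical amplicons among
  strains or copies of one species are not MAs). A species "has MAs" iff it
  appears in at least one group.
- **SC-NMA** = (species detected − species with MAs) / total species × 100.
  Dual-domain pairs are evaluated per domain and combined as
  Σ(detected − MA) / Σ(total) over the two domains ("overall SC-NMA").
- **OF / OF-MA** per species s with ≥1 amplicon:
  copies(s) = mean amplicons per detected unit of s; foreign(s) = mean
  per-unit count, over foreign units carrying at least one, of amplicons
  identical to one of s's amplicon sequences (0 if none);
  OF = copies + foreign; OF-MA = OF / copies. OF-MA ≥ 1 with equality iff
  the species has no MAs (tested as an invariant). The survey defines OF
  only by its boundary examples; this per-unit-mean reading reproduces all
  of them and is the documented interpretation.
- Percentages are rounded half-up (decimal) to 2 places at report time only;
  all internal computation is unrounded.

## 6. Synthetic communities (`silico16s.simulate`)

**Template.** A synthetic 1,550-nt 16S-like sequence built by constraint
propagation: per-position allowed sets start at {A,C,G,T}, are intersected
with the expansion sets of all 39 bundled primer binding sites (placed at
their printed reference positions; the six primers without printed positions
get positions chosen to approximate their published mean amplicon lengths),
and remaining freedom is resolved by a fixed-seed draw. It is **not** an
organismal sequence.

**Genomes.** I.i.d. uniform ACGT background with template-derived gene
copies inserted at non-overlapping positions (400-nt spacing); minus-strand
copies are inserted as reverse complements. Determinism: all randomness
derives from the spec seed via named substreams.

**Species identity.** Every unconstrained template segment ≥ 8 nt carries a
4-digit base-4 species code, so amplicons of different species always differ
somewhere in every primer window — except where an **MA link** deliberately
copies species A's amplified window for a named pair byte-identically into
species B. Linked windows are frozen against all further mutation in both
species. Note a link also forces MAs for any pair whose window is fully
contained in the linked window; truth tables account for this because they
are computed from the planted coordinates, not from the link list.

**Variants and divergence.** Variant j carries cumulative marker
substitutions at j fixed positions (outside all protected windows: primer
sites, terminal motifs, signature positions, linked windows), plus optional
random divergence substitutions at the configured per-base rate. Knockout
species get one substitution at a template position covered by exactly one
primer's site, chosen outside that letter's expansion set, making the
species undetectable by exactly the pairs using that primer.

**Truth tables** (gene/variant counts, per-pair detection, MA species,
SC-NMA, OF/OF-MA) are computed by direct slicing of the planted window
coordinates — an implementation independent of the pipeline's regex matching
path — and serve as the oracle for the acceptance tests. The bundled fixture
(`table1_like_spec`) spans copy numbers 1–11 and 1–9 variants over 18
species in two superkingdoms, with a five-chromosome genome, minus-strand
copies, an ambiguity-excluded decoy unit, one knockout species, and three MA
links.

## 7. Reporting (`silico16s.pipeline`, `silico16s.cli`)

One TSV dialect everywhere (UTF-8, tabs, '.' decimals, 2-decimal
percentages) so tests can diff outputs bit-exactly; identical config + seed
give byte-identical files. The run log records versions, seed, and counts at
every filtering step. The `worked-examples` command recomputes formula-level
values (SC-NMA, overall SC-NMA, copy-number band percentages, span lengths)
from count tables bundled with the package.

## Limitations

- PCR is an exact string model: no mismatch tolerance, thermodynamics,
  chimeras, or amplification bias; results are upper bounds on specificity
  effects, not yield predictions.
- The gene finder's constants (k, window, density, length range) are
  defaults chosen for robustness on the synthetic data model, not fitted to
  biological corpora; real-genome use should validate them or use the gene
  bypass with a trusted annotation.
- The simulator has no indel process, rate heterogeneity, or read-level
  error model; divergence is uniform substitution outside protected windows.
- Headline statistics of real genome collections (e.g., mean copies per
  genome of a published survey) require those genome sets and are out of
  scope; only formula-level values recomputable from printed counts are
  bundled and verified.
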