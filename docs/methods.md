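# Methods

This note documents the model behind `curatrack`, the defaults that
matter, the synthetic data the test suite runs on, and the design choices
made where the design was genuinely open.

## The tracked data model

The unit of tracking is an annotation entity at one of three levels:
genomic **locus**, **transcript** isoform, **subfeature** (exon/CDS).
Coordinates are 1-based fully closed throughout the library (the GFF3
convention); the single conversion to 0-based half-open happens in the
BED writer. Overlap of closed intervals is
`max(0, min(end_a, end_b) - max(start_a, start_b) + 1)` and is always
strand-blind; strand policy is a caller decision (entity queries take an
opt-in `same_strand` filter, conflict detection is strand-blind, because
evidence sources disagree on strand conventions far more often than on
coordinates).

Hierarchy rules: when a parent link is set, the parent must exist, be at
the immediately higher level, and contain the child's interval on the
same chromosome and strand. An *empty* parent link is legal at every
level, supporting degenerate flat projects (all transcripts under no
locus, subfeatures omitted) and partial exports. A transcript belongs to
at most one locus; read-through transcripts spanning two loci must be
modelled as their own locus.

The store is a single-file SQLite database (embedded, desk-scale, no
server), schema-versioned, with all multi-step operations wrapped in one
transaction. History is an append-only table; the API exposes no update
or delete for it, and every state-changing operation appends at least one
event. The event action vocabulary is `created`, `updated`,
`status_changed`, `priority_changed`, `flag_opened`, `flag_resolved`,
`flag_auto_resolved`, `comment_added`, `verify_changed`. An entity-field
update emits one `updated` event per changed field (interval counts as
one field) and silently moves the entity's status to `updated` as part of
the same operation.

## Evidence ingest

Three adaptors feed the store:

* **GFF3** (via `gffutils`): `gene → mRNA → exon/CDS` maps onto
  locus/transcript/subfeature. Records without `ID` get a synthesised id
  `source:chrom:start-end:type`; exon-level records without `Parent` are
  attached by containment to the unique containing transcript and
  rejected if ambiguous; transcript-level orphans are kept flat. A
  line-level pre-validation reports syntax errors with line numbers.
* **DAS 1.53E features XML** (stdlib ElementTree): `SEGMENT id` → chrom,
  `START`/`END` → interval, `ORIENTATION` (`+`/`-`/`0`) → strand,
  `TYPE`, `NOTE`, `TARGET id` → referential target. `verify_source`
  itemises every violation of the tight format (missing ids/TYPE/coords,
  non-integer or inverted coordinates, unknown orientation); a document
  that passes verification always parses. Strict sources fail loudly,
  lenient ones tolerate missing optional elements.
* **Flag files**: tab-delimited with a fixed five-column header
  (`target_entity_id  category  priority  source_name  comment`).
  Priorities are clamped to 0–5 with a logged warning; unknown target ids
  pass through and are held as *unmatched* flags that attach retroactively
  when the entity is imported.

Windowed retrieval tiles a region into consecutive **abutting** windows
(default 10 kb — small enough that a features document stays cheap even
in gene-dense regions, large enough to keep request counts sane
genome-wide). Abutting, not sliding: border deduplication only makes
sense for abutting tiles. The dedup key is
`(source, feature id, chrom, start, end, type)` — note text excluded, so
two identically placed features of different type are both kept. Each
window is attempted 3 times; windows that still fail are recorded and the
result is flagged partial. A partial cycle performs **zero**
auto-resolutions, because a conflict that "disappeared" with half the
data missing has not been resolved.

## Conflict detection

Comparisons are coordinate- and description-level only; no sequence, no
alignment, no splice-motif checking. For a positional feature:

1. no overlapping locus (strand-blind) → `novel_locus`, keyed on a
   synthetic region id `novel:chrom:start-end`;
2. exon-typed feature (`exon`, `CDS`) → clean if *any* overlapping
   transcript has a subfeature with both boundaries within tolerance,
   else `splice_mismatch`. Matching against every overlapping isoform
   rather than only the best-overlapping one is deliberate: with 2–4
   isoforms per locus, a correct exon of isoform B frequently
   best-overlaps isoform A and would otherwise be flagged spuriously;
3. other features → clean if any overlapping transcript shares at least
   one endpoint within tolerance, else `boundary_mismatch`;
4. a feature inside a locus but outside every transcript span →
   `boundary_mismatch` against the best-overlapping locus (it is not a
   novel locus — the region is annotated).

The flagged target is the transcript with maximal overlap, ties broken by
entity id. Referential features (carrying a target id) check
`reference_missing` first, then the same coordinate logic pinned to the
referenced entity, then the note against the stored description after
normalisation (case-fold, collapse whitespace, exact compare; fuzzy
matching would be a possible extension but exact-after-normalisation is
auditable).

Boundary tolerance defaults to 0 bases and is configurable per rule.
Default rule priorities: `reference_missing` 4, `splice_mismatch` 3,
`novel_locus` 3, `boundary_mismatch` 2, `description_mismatch` 1 — an
ordering by how actionable and how likely-real each conflict class is,
all configurable.

Conflict identity is the flag key `(target, category, source)`; detail
text is not part of the key, so a splice site shifted *again* retriggers
the existing flag rather than duplicating it. An update cycle is atomic
and priority-monotone: opening flags raises entity priorities to
`max(current, rule priority)` and auto-resolution never lowers them —
lowering urgency is a curator decision (manual resolution recomputes the
entity's priority as the max over its remaining open flags). Only
engine-opened flags of the same source are eligible for auto-resolution;
flags from flag files or the CLI are never auto-resolved, since
auto-resolution is defined by "the next data update of that source no
longer triggers the conflict", which says nothing about a manually filed
problem.

## Curation workflow

At most one open flag per key (enforced by a partial unique index);
re-raising escalates priority. The only legal transitions are
`open → accepted`, `open → declined` (manual, by a term's polarity) and
`open → auto_resolved` (engine, reserved term `auto_resolved`). Resolved
flags are immutable — correcting a mistake means opening a new flag,
preserving history fidelity. Bulk resolution validates every flag before
writing anything (all-or-nothing). The verification-pipeline marker
(`verify`) lives on the entity, not on a flag, since it selects
*transcripts* for wet-lab verification; the wet-lab results themselves
are out of scope beyond free-text comments.

The default resolution vocabulary is illustrative and user-replaceable in
the config file; it guarantees at least one accept and one decline term
per category (wildcard terms `annotation_updated` /
`external_data_rejected` backstop any custom category) and includes the
splice-specific accept term `annotated_splicing_corrected`.

## Reports

Statistics aggregate the flag table by chromosome (placing unmatched
flags via their entity, synthetic `novel:` keys via their embedded
chromosome, otherwise "(unplaced)"), by category, or by resolution term
(open flags grouped as "(open)"). Every grouping conserves the global
counts and `open + accepted + declined + auto_resolved` equals flags ever
created — resolved flags are never deleted, which is what makes the stats
usable as project-progress monitoring. Exports (BED with
`score = priority × 200` clamped to 1000, or GFF3 that re-imports
cleanly) are deterministically ordered, so identical stores yield
byte-identical files; a static file export replaces any live
feature-serving, which is out of scope.

## Synthetic data

The generator emulates a curation round: a reference gene set, an
external evidence view of it, and known injected disagreements. Defaults
are the study conditions used throughout the tests: 100 loci round-robin
across two 5 Mb chromosomes, 2–4 isoforms per locus, 2–5 exons per
transcript (exons 80–600 bp, introns 150–1500 bp, transcription starts
jittered ≤400 bp, inter-locus gaps 3–8 kb), perturbation shifts 1–20
bases (a 0-base shift would be undetectable at tolerance 0). Everything
is a pure function of the spec, seed included.

Perturbation targets are disjoint transcripts, so each injected conflict
maps to exactly one expected flag; expected targets for coordinate
perturbations are computed by the generator's own brute-force
maximal-overlap rule, and rejection sampling guarantees a perturbed
feature never accidentally coincides with another isoform's stored
coordinates and that all expected keys are distinct. The ground-truth
list is therefore complete and minimal at tolerance 0, and the acceptance
suite requires an update cycle to open *exactly* that list
(precision = recall = 1). `repair_evidence` reverts a seeded uniform
sample of perturbations, giving the exact expected auto-resolution set.

What the generator deliberately does **not** model: nucleotide sequence
(the tracker never touches it), overlapping or nested gene loci,
trans-splicing/read-through structures, evidence noise that is *not* a
conflict (e.g. coverage gaps), and clock skew between sources. Passing
tests therefore demonstrate the bookkeeping machinery — detection
exactness, idempotence, auto-resolution, auditability — on clean
geometry, not the biological difficulty of deciding whether a real
conflict is annotation error or evidence error; that judgement stays with
the curator.

## Problem sizes and numerics

The test suite and the acceptance script run the 100-locus study
(~1 400 entities, ~1 650 evidence features; an update cycle takes well
under a second), 200 randomized windowed-retrieval cases over regions up
to 1 Mb, 100 randomized stores for the query-vs-linear-scan oracle, and a
500-operation randomized workflow script with full invariant audits after
every operation. Determinism: all randomness is seeded (`random.Random`
seeded with strings derived from the spec seed); hypothesis-based
property tests run derandomised. Timestamps are UTC ISO-8601 and excluded
from determinism checks (exports contain no timestamps). Degenerate
inputs — empty stores, empty batches, empty flag files, single-base
intervals and windows — are covered by explicit tests.

## Known limitations

* Single-writer desk-scale store; no concurrent multi-user editing, no
  authentication (the actor is a plain string for the audit trail).
* Conflict detection is per-feature; it does not reason about whole
  transcript structures (e.g. an isoform with two shifted exons yields
  one retriggered flag per cycle, not two, because conflict identity is
  per target/category/source).
* Description comparison is exact after normalisation; near-duplicate
  wording is flagged.
* The DAS HTTP fetcher implements the plain 1.53E features command only
  (no registry discovery, no writeback, no stylesheets) and is exercised
  against local documents in the tests.
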