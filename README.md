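# curatrack

Issue tracking for collaborative genome annotation.

Large manual-annotation projects — a reference gene set built by many
groups from many evidence streams — need more than a genome browser and a
generic bug tracker: problems live on *genomic coordinates*, attach to a
**locus → transcript → subfeature** hierarchy, arrive continuously from
heterogeneous sources (partner DAS servers, GFF3 dumps, analysis
pipelines shipping tab-delimited lists of dubious splice sites), and must
be triaged, resolved with controlled vocabulary and audited over years.
`curatrack` is that tracker: it integrates evidence, detects conflicts
with the stored annotation, opens prioritised flags, drives a curator
workflow of accept/decline resolutions, and keeps an append-only history
plus progress statistics for the whole project.

It is aimed at annotation teams and their bioinformaticians: the library
is the API, and a `curatrack` command-line tool covers the day-to-day
operations.

## The model

* **Entities.** A tracked unit is a locus, transcript or subfeature
  (exon/CDS) with a 1-based closed `GenomicInterval`, a controlled status
  tag (`new`, `updated`, `rejected`, `experimentally_verified`, …) and an
  urgency priority 0–5. Containment and strand consistency are enforced
  whenever a parent link is set; flat (parentless transcript) projects are
  supported.
* **Evidence.** Sources are polled in abutting windows (default 10 kb);
  features spanning a window border are deduplicated on
  `(source, feature id, coordinates, type)`. Documents can be verified
  against a tight DAS 1.53E features schema before use.
* **Conflicts.** Evidence is compared on coordinates and descriptions
  only. Positional features yield `novel_locus` (no overlapping locus),
  `splice_mismatch` (exon evidence matching no annotated exon boundary
  within tolerance, default 0 bases) or `boundary_mismatch`; referential
  features add `reference_missing` and `description_mismatch` (exact
  comparison after case-folding and whitespace collapse). A conflict's
  identity is its flag key `(target, category, source)`.
* **Flags.** At most one open flag per key; re-raising escalates priority
  instead of duplicating. An entity's priority tracks the maximum over
  its open flags. Manual resolution uses a controlled term whose polarity
  (accept/decline) decides the final state; engine-opened flags whose
  conflict is not re-triggered by the source's next *complete* update are
  closed automatically (`auto_resolved`). Partial updates (failed
  windows) never auto-resolve anything.
* **History.** Every state change appends an immutable event (actor,
  timestamp, before/after); nothing can rewrite it.

## Worked example

The built-in synthetic generator builds a deterministic reference set
(100 loci, 2–4 isoforms each, on two 5 Mb chromosomes) and an evidence
view with 20 splice-site shifts and 10 novel-region features injected:

```python
from curatrack import (AnnotationStore, PerturbationSpec, SourceConfig,
                       generate_annotation, generate_evidence, load_entities,
                       run_update_cycle, resolve_flag, stats)
from curatrack.reports import format_stats_table

spec = PerturbationSpec(seed=1, n_loci=100, n_splice_shifts=20, n_novel_loci=10)
annotation = generate_annotation(spec)
evidence = generate_evidence(annotation, spec)

store = AnnotationStore(":memory:")
load_entities(store, annotation.entities)
store.register_source(SourceConfig(spec.source_name, "das"))

report = run_update_cycle(store, spec.source_name, evidence.features)
print(f"cycle {report.cycle_id}: opened={len(report.opened)} "
      f"retriggered={len(report.retriggered)} auto_resolved={len(report.auto_resolved)}")

flag = store.open_flags()[0]
resolve_flag(store, flag.flag_id, "annotated_splicing_corrected",
             "annotator1", comment="splice sites updated upstream")
print(format_stats_table(stats(store, group_by="category")))
```

prints

```
cycle 1: opened=30 retriggered=0 auto_resolved=0
group            open  accepted  declined  auto_resolved  total  entities_open
novel_locus      10    0         0         0              10     0
splice_mismatch  19    1         0         0              20     19
```

All 30 injected conflicts were recovered (and nothing else was flagged);
one splice flag was then accepted with the controlled term
`annotated_splicing_corrected`, which the statistics page reflects. Running
the same cycle again would open 0 flags and retrigger 30; repairing some
perturbations in the evidence and cycling once more auto-resolves exactly
the repaired keys.

The same flow from a shell:

```
curatrack --db track.db import-annotation annotation.gff3
curatrack --db track.db update --source external_das --das evidence.das.xml
curatrack --db track.db find --region chr1:1-5000000 --category splice_mismatch
curatrack --db track.db flags resolve 3 --term annotated_splicing_corrected
curatrack --db track.db stats --by chromosome
curatrack --db track.db export --format bed --min-priority 4 -o urgent.bed
```

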