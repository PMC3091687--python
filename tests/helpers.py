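"""Shared test utilities: randomized stores and brute-force oracles."""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Set, Tuple

from curatrack.ingest.flagfile import FlagRequest
from curatrack.model import AnnotationEntity, GenomicInterval, interval_overlap
from curatrack.store import AnnotationStore
from curatrack.workflow import open_flag

CHROMS = ("chr1", "chr2", "chr3")
CATEGORIES = ("splice", "splice_mismatch", "boundary_mismatch", "novel_locus")
KEYWORDS = ("kinase", "olfactory", "histone", "ribosomal")
STATUSES = ("new", "updated", "rejected", "experimentally_verified")


def random_store(rng: random.Random, max_loci: int = 60) -> AnnotationStore:
    """A store of random loci/transcripts with random statuses and flags.

    Loci may overlap each other (the store does not forbid it); transcripts
    lie within their locus; a sprinkling of transcripts is parentless
    (degenerate flat configuration). Some transcripts get open flags.
    """
    store = AnnotationStore()
    n_loci = rng.randint(5, max_loci)
    eid = 0
    transcript_ids = []
    with store.transaction():
        for _ in range(n_loci):
            chrom = rng.choice(CHROMS)
            strand = rng.choice("+-")
            start = rng.randint(1, 500_000)
            end = start + rng.randint(500, 20_000)
            eid += 1
            locus_id = f"E{eid:05d}"
            store.upsert_entity(AnnotationEntity(
                locus_id, "locus", GenomicInterval(chrom, start, end, strand),
                description=f"locus like {rng.choice(KEYWORDS)}"))
            for _ in range(rng.randint(0, 3)):
                t_start = rng.randint(start, end - 100)
                t_end = t_start + rng.randint(50, end - t_start)
                eid += 1
                tid = f"E{eid:05d}"
                store.upsert_entity(AnnotationEntity(
                    tid, "transcript", GenomicInterval(chrom, t_start, t_end, strand),
                    parent_id=locus_id,
                    description=f"{rng.choice(KEYWORDS)} transcript"))
                transcript_ids.append(tid)
        for _ in range(rng.randint(0, 5)):  # parentless transcripts
            chrom = rng.choice(CHROMS)
            start = rng.randint(1, 900_000)
            eid += 1
            tid = f"E{eid:05d}"
            store.upsert_entity(AnnotationEntity(
                tid, "transcript",
                GenomicInterval(chrom, start, start + rng.randint(100, 5000),
                                rng.choice(("+", "-", "."))),
                description="orphan transcript"))
            transcript_ids.append(tid)
    for tid in transcript_ids:
        if rng.random() < 0.3:
            store.set_status(tid, rng.choice(STATUSES[1:]), actor="tester")
        if rng.random() < 0.4:
            open_flag(store,
                      FlagRequest(tid, rng.choice(CATEGORIES), rng.randint(1, 5),
                                  "testsource", "injected"),
                      actor="tester")
    return store


def brute_force_find(
    store: AnnotationStore,
    region: Optional[GenomicInterval] = None,
    level: Optional[str] = None,
    status: Optional[str] = None,
    flag_category: Optional[str] = None,
    keyword: Optional[str] = None,
    min_priority: Optional[int] = None,
) -> List[AnnotationEntity]:
    """Independent linear-scan oracle for AnnotationStore.find_entities."""
    open_keys: Set[Tuple[str, str]] = {
        (f.target_entity_id, f.category)
        for f in store.open_flags() if not f.unmatched
    }
    out = []
    for e in store.all_entities():
        if region is not None and interval_overlap(e.interval, region) < 1:
            continue
        if level is not None and e.level != level:
            continue
        if status is not None and e.status != status:
            continue
        if min_priority is not None and e.priority < min_priority:
            continue
        if flag_category is not None and (e.entity_id, flag_category) not in open_keys:
            continue
        if keyword is not None:
            hay = (e.entity_id + "\x00" + e.description).lower()
            if keyword.lower() not in e.entity_id.lower() \
                    and keyword.lower() not in e.description.lower():
                continue
        out.append(e)
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.entity_id))
    return out


def random_query(rng: random.Random) -> Dict:
    """A random predicate combination for the find oracle."""
    query: Dict = {}
    if rng.random() < 0.5:
        chrom = rng.choice(CHROMS)
        start = rng.randint(1, 400_000)
        query["region"] = GenomicInterval(chrom, start, start + rng.randint(1000, 400_000))
    if rng.random() < 0.3:
        query["level"] = rng.choice(("locus", "transcript"))
    if rng.random() < 0.3:
        query["status"] = rng.choice(STATUSES)
    if rng.random() < 0.3:
        query["flag_category"] = rng.choice(CATEGORIES)
    if rng.random() < 0.3:
        query["keyword"] = rng.choice(KEYWORDS)
    if rng.random() < 0.3:
        query["min_priority"] = rng.randint(1, 5)
    return query
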