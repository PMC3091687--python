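"""Windowed feature retrieval with border deduplication.

Genome-scale sources are polled in consecutive windows (default 10 kb)
rather than one huge query; a feature spanning a window border is
returned by both windows and must appear exactly once downstream. The
dedup key is ``(source_name, feature_id, chrom, start, end, type)`` —
deliberately *excluding* the note text, so two identically placed
features of different type are both kept while a border duplicate is
dropped.

Fetchers are pluggable: anything with ``fetch(chrom, start, end) ->
list[SourceFeature]`` works. Bundled implementations serve an in-memory
feature list, a local DAS XML document, and plain HTTP GET of the 1.53E
features command.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from typing import Dict, List, Protocol, Sequence, Tuple

from ..errors import ConfigError
from ..model import GenomicInterval, interval_overlap
from .base import SourceFeature
from .das import read_das_features

__all__ = [
    "Fetcher",
    "StaticFetcher",
    "DASFileFetcher",
    "HTTPDASFetcher",
    "WindowedFetchResult",
    "tile_region",
    "dedup_features",
    "fetch_windowed",
]

DEFAULT_WINDOW_SIZE = 10000


class Fetcher(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> List[SourceFeature]:
        ...


class StaticFetcher:
    """Serves an in-memory feature list; answers with every feature
    overlapping the queried range. Records queries for test inspection."""

    def __init__(self, features: Sequence[SourceFeature]):
        self.features = list(features)
        self.calls: List[Tuple[str, int, int]] = []

    def fetch(self, chrom: str, start: int, end: int) -> List[SourceFeature]:
        self.calls.append((chrom, start, end))
        window = GenomicInterval(chrom, start, end)
        return [f for f in self.features if interval_overlap(f.interval, window) > 0]


class DASFileFetcher(StaticFetcher):
    """Serves a local DAS features XML document as if it were a server."""

    def __init__(self, path: str, source_name: str = "das"):
        super().__init__(read_das_features(path, source_name=source_name))


class HTTPDASFetcher:
    """Plain HTTP GET of the DAS 1.53E features command.

    ``base_url`` is the DAS source root (``.../das/<source>``); the
    features request appends ``/features?segment=chrom:start,end``.
    """

    def __init__(self, base_url: str, source_name: str = "das", timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.source_name = source_name
        self.timeout = timeout

    def fetch(self, chrom: str, start: int, end: int) -> List[SourceFeature]:
        url = f"{self.base_url}/features?segment={chrom}:{start},{end}"
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            document = resp.read().decode("utf-8")
        return read_das_features(document, source_name=self.source_name)


@dataclass
class WindowedFetchResult:
    """Outcome of one windowed retrieval. ``failures`` lists the windows
    that could not be read after retries; a result with failures must be
    treated as partial (the conflict engine skips auto-resolution)."""

    features: List[SourceFeature]
    windows: List[Tuple[int, int]]
    failures: List[Dict] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures


def tile_region(region: GenomicInterval, window_size: int) -> List[Tuple[int, int]]:
    """Consecutive abutting windows covering the region; last one truncated."""
    if window_size < 1:
        raise ConfigError(f"window_size must be >= 1, got {window_size}")
    windows = []
    pos = region.start
    while pos <= region.end:
        windows.append((pos, min(pos + window_size - 1, region.end)))
        pos += window_size
    return windows


def dedup_features(features: Sequence[SourceFeature]) -> List[SourceFeature]:
    """Drop border duplicates; deterministic (chrom, start, feature_id) order."""
    seen = set()
    unique: List[SourceFeature] = []
    for f in features:
        key = (f.source_name, f.feature_id, f.interval.chrom,
               f.interval.start, f.interval.end, f.type)
        if key in seen:
            continue
        seen.add(key)
        unique.append(f)
    unique.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.feature_id))
    return unique


def fetch_windowed(fetcher: Fetcher, region: GenomicInterval,
                   window_size: int = DEFAULT_WINDOW_SIZE,
                   retries: int = 3) -> WindowedFetchResult:
    """Fetch a region window-by-window, deduplicating border spanners.

    Each window is attempted up to ``retries`` times; a window that still
    fails is recorded in ``failures`` and the result is flagged partial —
    it is never silently returned as complete.
    """
    windows = tile_region(region, window_size)
    collected: List[SourceFeature] = []
    failures: List[Dict] = []
    for (wstart, wend) in windows:
        last_error = None
        for _ in range(retries):
            try:
                collected.extend(fetcher.fetch(region.chrom, wstart, wend))
                last_error = None
                break
            except Exception as exc:  # noqa: BLE001 - fetcher faults are data, not bugs
                last_error = exc
        if last_error is not None:
            failures.append({"window": (region.chrom, wstart, wend),
                             "error": str(last_error)})
    return WindowedFetchResult(features=dedup_features(collected),
                               windows=windows, failures=failures)
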