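"""YAML configuration: sources, conflict rules, vocabularies.

Example::

    window_size: 10000
    sources:
      - source_name: partner_das
        kind: das
        locator: http://example.org/das/partner
        window_size: 10000
        schema_strict: true
    rules:
      splice_mismatch: {priority: 3, tolerance: 0}
      boundary_mismatch: {priority: 2, tolerance: 0}
    status_vocabulary: [new, updated, rejected, experimentally_verified]
    resolution_vocabulary:
      - {term: annotated_splicing_corrected, polarity: accept,
         categories: [splice_mismatch, splice]}

Every block is optional; omitted blocks fall back to the built-in
defaults, and partial rule entries override only the fields they name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from .conflicts import ConflictRule, default_rules
from .errors import ConfigError
from .ingest.base import SourceConfig
from .model import StatusVocabulary
from .workflow import ResolutionTerm, ResolutionVocabulary

__all__ = ["TrackerConfig", "load_config"]


@dataclass
class TrackerConfig:
    sources: Dict[str, SourceConfig] = field(default_factory=dict)
    rules: Dict[str, ConflictRule] = field(default_factory=default_rules)
    status_vocabulary: StatusVocabulary = field(default_factory=StatusVocabulary.default)
    resolution_vocabulary: ResolutionVocabulary = field(
        default_factory=ResolutionVocabulary.default)


def load_config(path_or_text: str) -> TrackerConfig:
    """Load a YAML config file (or literal YAML text)."""
    text = str(path_or_text)
    if "\n" not in text and ":" not in text:
        with open(text) as fh:
            text = fh.read()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"unreadable config: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    config = TrackerConfig()
    default_window = int(data.get("window_size", 10000))

    for entry in data.get("sources", []) or []:
        if not isinstance(entry, dict):
            raise ConfigError(f"source entry must be a mapping, got {entry!r}")
        entry = dict(entry)
        entry.setdefault("window_size", default_window)
        try:
            source = SourceConfig(**entry)
        except TypeError as exc:
            raise ConfigError(f"bad source entry {entry!r}: {exc}") from exc
        if source.source_name in config.sources:
            raise ConfigError(f"duplicate source {source.source_name!r}")
        config.sources[source.source_name] = source

    rules = default_rules()
    for category, settings in (data.get("rules", {}) or {}).items():
        settings = dict(settings or {})
        base = rules.get(category)
        priority = int(settings.pop("priority",
                                    base.priority if base else 1))
        auto = bool(settings.pop("auto_resolvable",
                                 base.auto_resolvable if base else True))
        params = dict(base.parameters) if base else {}
        params.update({k: int(v) for k, v in settings.items()})
        rules[category] = ConflictRule(category, priority,
                                       tuple(sorted(params.items())), auto)
    config.rules = rules

    if "status_vocabulary" in data:
        config.status_vocabulary = StatusVocabulary(tuple(data["status_vocabulary"]))
    if "resolution_vocabulary" in data:
        terms = []
        for entry in data["resolution_vocabulary"]:
            terms.append(ResolutionTerm(entry["term"], entry["polarity"],
                                        tuple(entry["categories"])))
        config.resolution_vocabulary = ResolutionVocabulary(tuple(terms))
    return config
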