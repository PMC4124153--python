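"""End-to-end conversion: read → detect → normalize → map → emit.

Two modes mirror the two ways a conversion can be configured:

* **auto mode** — for class-detectable data (any DwC-A, or a CSV whose
  headers are vocabulary terms) the four configuration steps are completed
  automatically and the mapping can be exported for later reuse;
* **mapping mode** — a previously saved (possibly hand-edited) mapping file
  drives the conversion, either over the normalized per-class tables it was
  exported against or over the raw source tables it names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .emit import TripleGraph, emit as _emit
from .errors import MappingError
from .mapping import MappingConfig, build_auto_mapping
from .normalize import NormalizedDataset, normalize_archive, normalize_table
from .relations import ClassGraph, load_class_graph
from .tabular import DEFAULT_REGISTRY, DwcArchive, SourceTable
from .vocabulary import Vocabulary, load_vocabulary


@dataclass
class ConversionResult:
    graph: TripleGraph
    config: MappingConfig
    normalized: NormalizedDataset | None
    report: dict


def convert(
    path: str | Path,
    *,
    format: str | None = None,
    mapping: MappingConfig | None = None,
    vocab: Vocabulary | None = None,
    class_graph: ClassGraph | None = None,
    base_uri: str = "http://example.org/id/",
    strict: bool = False,
    prelude: bool = True,
) -> ConversionResult:
    """Convert one input file to a triple graph."""
    vocab = vocab if vocab is not None else load_vocabulary()
    class_graph = class_graph if class_graph is not None else load_class_graph()
    if strict:
        import contextlib
        ctx = warnings.catch_warnings()
        ctx.__enter__()
        warnings.simplefilter("error")
    else:
        ctx = None
    try:
        source = DEFAULT_REGISTRY.read(path, format)
    finally:
        if ctx is not None:
            ctx.__exit__(None, None, None)

    normalized: NormalizedDataset | None = None
    if isinstance(source, DwcArchive):
        normalized = normalize_archive(source, vocab, strict=strict)
        tables = normalized.source_tables()
        links = normalized.link_table()
    else:
        assert isinstance(source, SourceTable)
        raw_tables = {source.name: source}
        if mapping is not None and all(
            e.table in raw_tables for e in mapping.entities
        ):
            tables, links = raw_tables, None
        else:
            normalized = normalize_table(source, vocab, strict=strict)
            tables = normalized.source_tables()
            links = normalized.link_table()

    if mapping is None:
        if normalized is None:
            raise MappingError("auto mode requires class-detectable input")
        config = build_auto_mapping(normalized, vocab, class_graph, base_uri)
    else:
        config = mapping
        if config.fingerprint:
            actual = {name: t.headers for name, t in sorted(tables.items())}
            if config.fingerprint != actual:
                warnings.warn(
                    f"{Path(path).name}: dataset structure differs from the one "
                    "the mapping file was generated for"
                )

    graph = _emit(tables, config, links, vocab, prelude=prelude)
    report = normalized.report() if normalized is not None else {
        "classes_detected": [], "link_rows": None
    }
    report["triples"] = len(graph)
    return ConversionResult(graph=graph, config=config,
                            normalized=normalized, report=report)
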