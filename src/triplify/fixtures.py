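"""Seeded synthetic Darwin Core Archives with known ground truth.

The generator writes a conformant occurrence-core DwC-A (meta.xml plus a CSV
core file) whose columns are genuine Darwin Core terms for a requested set
of classes, and alongside it a manifest recording exactly what a correct
conversion must produce: per-class instance counts after deduplication, the
number of link tuples, distinct related-instance pair counts per class-graph
edge, and the occurrence IRIs that end up connected to a Taxon instance.

Only the structure of biodiversity data is modeled — duplication rates,
missing cells, explicit-versus-local identifiers — not its content: values
come from small fixed pools so duplication is controllable, and all
randomness is driven by the spec's seed (same spec, byte-identical archive).
"""

from __future__ import annotations

import json
import random
import urllib.parse
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .normalize import table_name_for_class

OCCURRENCE = "http://rs.tdwg.org/dwc/terms/Occurrence"
EVENT = "http://rs.tdwg.org/dwc/terms/Event"
LOCATION = "http://purl.org/dc/terms/Location"
GEOLOGICALCONTEXT = "http://rs.tdwg.org/dwc/terms/GeologicalContext"
IDENTIFICATION = "http://rs.tdwg.org/dwc/terms/Identification"
TAXON = "http://rs.tdwg.org/dwc/terms/Taxon"

DWC = "http://rs.tdwg.org/dwc/terms/"

#: the literal (non-ID) columns generated per class, with their term URIs
CLASS_COLUMNS: dict[str, list[tuple[str, str]]] = {
    OCCURRENCE: [("catalogNumber", DWC + "catalogNumber"),
                 ("recordedBy", DWC + "recordedBy")],
    EVENT: [("eventDate", DWC + "eventDate"), ("habitat", DWC + "habitat")],
    LOCATION: [("locality", DWC + "locality"), ("country", DWC + "country")],
    GEOLOGICALCONTEXT: [("formation", DWC + "formation")],
    IDENTIFICATION: [("identifiedBy", DWC + "identifiedBy")],
    TAXON: [("scientificName", DWC + "scientificName"),
            ("family", DWC + "family")],
}

ID_COLUMNS: dict[str, tuple[str, str]] = {
    OCCURRENCE: ("occurrenceID", DWC + "occurrenceID"),
    EVENT: ("eventID", DWC + "eventID"),
    LOCATION: ("locationID", DWC + "locationID"),
    GEOLOGICALCONTEXT: ("geologicalContextID", DWC + "geologicalContextID"),
    IDENTIFICATION: ("identificationID", DWC + "identificationID"),
    TAXON: ("taxonID", DWC + "taxonID"),
}

# small fixed value pools; distinctness is forced with an index suffix
_POOLS = {
    "catalogNumber": ["CAT-7", "CAT-12", "CAT-40"],
    "recordedBy": ["A. Wallace", "M. Merian", "C. Darwin"],
    "eventDate": ["1998-04-12", "2003-07-30", "2011-01-05"],
    "habitat": ["riparian forest", "alpine meadow", "coastal dune"],
    "locality": ["Sagehen Creek", "Mount Mitchell", "Pine Barrens"],
    "country": ["United States", "Mexico", "Canada"],
    "formation": ["Morrison", "Green River", "Hell Creek"],
    "identifiedBy": ["R. Fisher", "E. Mayr", "L. Agassiz"],
    "scientificName": ["Quercus alba", "Peromyscus maniculatus", "Danaus plexippus"],
    "family": ["Fagaceae", "Cricetidae", "Nymphalidae"],
}

#: the class-to-class edges a default conversion will emit, given which
#: classes are present (mirrors the bundled class graph + Event fallback)
_DEFAULT_EDGES = [
    (OCCURRENCE, "http://biscicol.org/terms/biscicol.owl#related_to", TAXON),
    (IDENTIFICATION, "http://biscicol.org/terms/biscicol.owl#depends_on", OCCURRENCE),
    (IDENTIFICATION, "http://biscicol.org/terms/biscicol.owl#related_to", TAXON),
    (OCCURRENCE, "http://biscicol.org/terms/biscicol.owl#depends_on", EVENT),
    (EVENT, "http://biscicol.org/terms/biscicol.owl#related_to", LOCATION),
    (EVENT, "http://biscicol.org/terms/biscicol.owl#related_to", GEOLOGICALCONTEXT),
]


@dataclass
class FixtureSpec:
    n_rows: int
    classes: tuple[str, ...] = (OCCURRENCE, TAXON)
    explicit_id_classes: tuple[str, ...] = (OCCURRENCE,)
    duplicate_fraction: dict[str, float] = field(default_factory=dict)
    missing_cell_fraction: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    base_uri: str = "http://example.org/id/"

    def __post_init__(self):
        if OCCURRENCE not in self.classes:
            raise ValueError("fixture archives are occurrence cores; "
                             "classes must include Occurrence")
        if OCCURRENCE not in self.explicit_id_classes:
            self.explicit_id_classes = (OCCURRENCE,) + tuple(self.explicit_id_classes)
        for name, frac in {**self.duplicate_fraction,
                           **self.missing_cell_fraction}.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name!r} outside [0, 1]: {frac}")
        if self.n_rows < 0:
            raise ValueError("n_rows must be >= 0")


def _instance_pool(cls: str, size: int, explicit: bool, rng: random.Random):
    """``size`` distinct instances of a class: (id or None, literal tuple)."""
    local = table_name_for_class(cls)
    columns = CLASS_COLUMNS[cls]
    pool = []
    for i in range(size):
        values = tuple(
            f"{_POOLS[header][i % len(_POOLS[header])]} {i + 1}"
            if size > len(_POOLS[header]) else _POOLS[header][i]
            for header, _term in columns
        )
        ident = f"{local.upper()}{i + 1:04d}" if explicit else None
        pool.append((ident, values))
    return pool


def generate_dwca(spec: FixtureSpec, path: str | Path) -> dict:
    """Write the archive and its ground-truth manifest; returns the manifest.

    The manifest is also written next to the archive as ``<stem>.manifest.json``.
    """
    path = Path(path)
    rng = random.Random(spec.seed)
    n = spec.n_rows

    headers: list[str] = []
    terms: list[str] = []
    for cls in spec.classes:
        if cls in spec.explicit_id_classes:
            h, t = ID_COLUMNS[cls]
            headers.append(h)
            terms.append(t)
        for h, t in CLASS_COLUMNS[cls]:
            headers.append(h)
            terms.append(t)

    # choose which rows carry data for each class, and which instance
    present_rows: dict[str, set[int]] = {}
    assignment: dict[str, dict[int, tuple]] = {}
    pool_used: dict[str, int] = {}
    for cls in spec.classes:
        missing = spec.missing_cell_fraction.get(cls, 0.0)
        if cls == OCCURRENCE:
            missing = 0.0  # the hub record is always present
        n_with = n - round(missing * n)
        rows_with = sorted(rng.sample(range(n), n_with)) if n else []
        present_rows[cls] = set(rows_with)
        dup = spec.duplicate_fraction.get(cls, 0.0)
        pool_size = max(1, n_with - round(dup * n_with)) if n_with else 0
        pool = _instance_pool(cls, pool_size,
                              cls in spec.explicit_id_classes, rng)
        chosen: dict[int, tuple] = {}
        for j, row in enumerate(rows_with):
            # first pass uses every pool member once, so the count of
            # distinct instances is exactly the pool size
            chosen[row] = pool[j] if j < pool_size else pool[rng.randrange(pool_size)]
        assignment[cls] = chosen
        pool_used[cls] = min(pool_size, n_with)

    # assemble the core rows
    rows = []
    for i in range(n):
        cells = []
        for cls in spec.classes:
            if i in present_rows[cls]:
                ident, values = assignment[cls][i]
            else:
                ident, values = None, tuple("" for _ in CLASS_COLUMNS[cls])
            if cls in spec.explicit_id_classes:
                cells.append(ident or "")
            cells.extend(values)
        rows.append(cells)

    _write_archive(path, headers, terms, rows)
    manifest = _build_manifest(spec, present_rows, assignment, pool_used)
    manifest_file = path.parent / (path.stem + ".manifest.json")
    manifest_file.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    return manifest


def _write_archive(path: Path, headers, terms, rows) -> None:
    fields = "\n".join(
        f'    <field index="{i}" term="{t}"/>' for i, t in enumerate(terms)
    )
    meta = f"""<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core encoding="UTF-8" fieldsTerminatedBy="," linesTerminatedBy="\\n"
        fieldsEnclosedBy="&quot;" ignoreHeaderLines="1"
        rowType="http://rs.tdwg.org/dwc/terms/Occurrence">
    <files><location>occurrence.csv</location></files>
    <id index="0"/>
{fields}
  </core>
</archive>
"""
    def fmt(cell: str) -> str:
        if any(ch in cell for ch in ',"\n'):
            return '"' + cell.replace('"', '""') + '"'
        return cell

    lines = [",".join(headers)] + [",".join(fmt(c) for c in row) for row in rows]
    data = "\n".join(lines) + "\n"
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, payload in (("meta.xml", meta), ("occurrence.csv", data)):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, payload)


def _build_manifest(spec, present_rows, assignment, pool_used) -> dict:
    n = spec.n_rows
    instance_counts = {
        table_name_for_class(cls): pool_used[cls] for cls in spec.classes
    }

    def instance_id(cls: str, row: int) -> str:
        ident, values = assignment[cls][row]
        return ident if ident is not None else "\x00" + "\x00".join(values)

    # which edges apply, mirroring auto-mapping (Event fallback to the hub)
    edges = []
    for s, p, o in _DEFAULT_EDGES:
        if EVENT not in spec.classes:
            if s == EVENT:
                s = OCCURRENCE
            elif o == EVENT:
                o = OCCURRENCE
        if s in spec.classes and o in spec.classes and s != o:
            if (s, p, o) not in edges:
                edges.append((s, p, o))

    link_counts = {}
    for s, p, o in edges:
        pairs = {
            (instance_id(s, i), instance_id(o, i))
            for i in range(n)
            if i in present_rows[s] and i in present_rows[o]
        }
        key = f"{table_name_for_class(s)}|{p.rsplit('#', 1)[-1]}|{table_name_for_class(o)}"
        link_counts[key] = len(pairs)

    # non-empty cells surviving deduplication = literal triples emitted
    literal_cells = 0
    for cls in spec.classes:
        seen = set()
        for i in sorted(present_rows[cls]):
            key = instance_id(cls, i)
            if key in seen:
                continue
            seen.add(key)
            _ident, values = assignment[cls][i]
            literal_cells += sum(1 for v in values if v.strip())

    occ_with_taxa = []
    if TAXON in spec.classes:
        occ_col, _ = ID_COLUMNS[OCCURRENCE]
        seen_ids = set()
        for i in sorted(present_rows[TAXON] & present_rows[OCCURRENCE]):
            ident, _values = assignment[OCCURRENCE][i]
            if ident in seen_ids:
                continue
            seen_ids.add(ident)
            composed = f"occurrence.{occ_col}_{ident}"
            occ_with_taxa.append(spec.base_uri + urllib.parse.quote(composed, safe=""))

    return {
        "n_rows": n,
        "instance_counts": instance_counts,
        "link_counts": link_counts,
        "literal_triples": literal_cells,
        "expected_occurrences_with_taxa": sorted(occ_with_taxa),
    }
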