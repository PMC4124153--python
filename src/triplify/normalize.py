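"""Splitting a flat table into per-class instance tables.

A flat occurrence table mixes columns describing several kinds of things: the
occurrence record itself, the collecting event, the locality, the taxon, and
so on.  Normalization (in the database sense) undoes that flattening:

1. :func:`detect_classes` resolves each column header (or the term URI a
   DwC-A descriptor attaches to it) to a vocabulary term and thence to the
   class the term is organized in;
2. :func:`normalize` projects every source row onto each present class's
   columns, drops empty projections, and collapses duplicate instances —
   keyed by the explicit identifier where the class has an ID column
   (``occurrenceID`` …), by the full value tuple otherwise;
3. :func:`assign_local_ids` numbers the instances of classes that have no
   identifier column at all with local integer identifiers 1..n in first
   appearance order.

The co-occurrence of class instances on each source row is preserved in a
link table, which later drives relationship-triple emission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import NormalizationError, StrictModeError
from .tabular import Column, DwcArchive, SourceTable
from .vocabulary import TermKind, Vocabulary

#: sentinel key prefix never colliding with real identifier values
_TUPLE_KEY = "\x00"


def table_name_for_class(class_uri: str) -> str:
    """Normalized per-class table name, e.g. ``…/Occurrence`` -> "occurrence"."""
    return class_uri.rstrip("/").rsplit("/", 1)[-1].split("#")[-1].lower()


@dataclass
class ClassAssignment:
    """Column-to-class resolution for one source table."""

    column_class: dict[int, str | None]
    id_column_index: dict[str, int] = field(default_factory=dict)
    column_term: dict[int, str] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    @property
    def present_classes(self) -> list[str]:
        seen: list[str] = []
        for cls in self.column_class.values():
            if cls is not None and cls not in seen:
                seen.append(cls)
        return seen

    def has_explicit_id(self, class_uri: str) -> bool:
        return class_uri in self.id_column_index


def detect_classes(table: SourceTable, vocab: Vocabulary) -> ClassAssignment:
    """Resolve each column to the class it describes.

    Unknown headers and record-level terms without a single-class domain are
    left unassigned (reported, never an error).  An ID-term column marks its
    class as having explicit identifiers.
    """
    from .errors import AmbiguousTermError

    assignment = ClassAssignment(column_class={})
    for i, col in enumerate(table.columns):
        term = None
        if col.term_uri:
            term = vocab.terms.get(col.term_uri)
        if term is None:
            try:
                term = vocab.term_for_column(col.header)
            except AmbiguousTermError as exc:
                warnings.warn(f"column {col.header!r} left unassigned: {exc}")
                term = None
        if term is None or term.kind is TermKind.CLASS:
            assignment.column_class[i] = None
            assignment.unassigned.append(col.header)
            continue
        cls = vocab.class_of_term(term.uri)
        if cls is None:  # domainless record-level term
            assignment.column_class[i] = None
            assignment.unassigned.append(col.header)
            continue
        assignment.column_class[i] = cls
        assignment.column_term[i] = term.uri
        if term.kind is TermKind.ID_TERM and cls not in assignment.id_column_index:
            assignment.id_column_index[cls] = i
    return assignment


@dataclass
class InstanceTable:
    """Deduplicated instances of one class."""

    class_uri: str
    table_name: str
    id_column: str
    explicit: bool
    literal_columns: list[Column]
    #: instance key -> literal value tuple, in first-appearance order
    instances: dict[str | tuple, tuple[str, ...]] = field(default_factory=dict)
    #: instance key -> identifier string (after assign_local_ids)
    ids: dict[str | tuple, str] = field(default_factory=dict)
    duplicate_rows: int = 0
    id_conflicts: list[str] = field(default_factory=list)


@dataclass
class NormalizedDataset:
    tables: dict[str, InstanceTable] = field(default_factory=dict)  # class -> table
    #: one tuple per source row: class URI -> instance key (or None)
    link_rows: list[dict[str, object]] = field(default_factory=list)
    hub_class: str | None = None
    unassigned_columns: list[str] = field(default_factory=list)

    def report(self) -> dict:
        """Normalization summary: classes, duplicates, conflicts."""
        return {
            "classes_detected": sorted(self.tables),
            "unassigned_columns": list(self.unassigned_columns),
            "instance_counts": {
                t.table_name: len(t.instances) for t in self.tables.values()
            },
            "duplicate_rows": {
                t.table_name: t.duplicate_rows for t in self.tables.values()
            },
            "id_conflicts": {
                t.table_name: list(t.id_conflicts) for t in self.tables.values()
            },
            "link_rows": len(self.link_rows),
        }

    # -- views used by mapping/emission -----------------------------------

    def source_tables(self) -> dict[str, SourceTable]:
        """Instance tables as plain tables (identifier column first)."""
        out = {}
        for it in self.tables.values():
            if any(k not in it.ids for k in it.instances):
                raise NormalizationError(
                    f"{it.table_name}: identifiers not assigned yet"
                )
            cols = [Column(it.id_column)] + it.literal_columns
            rows = [
                (it.ids[key],) + values for key, values in it.instances.items()
            ]
            out[it.table_name] = SourceTable(it.table_name, cols, rows)
        return out

    def link_table(self) -> list[dict[str, str]]:
        """Per-source-row identifier tuples keyed by instance table name."""
        out = []
        for row in self.link_rows:
            entry = {}
            for cls, key in row.items():
                if key is None:
                    continue
                it = self.tables[cls]
                entry[it.table_name] = it.ids[key]
            out.append(entry)
        return out


def normalize(table: SourceTable, assignment: ClassAssignment,
              *, strict: bool = False) -> NormalizedDataset:
    """Project rows onto per-class instance tables and deduplicate."""
    present = assignment.present_classes
    if not present:
        raise NormalizationError(
            f"table {table.name!r}: no vocabulary classes detected in its columns"
        )
    ds = NormalizedDataset(unassigned_columns=list(assignment.unassigned))

    per_class_cols: dict[str, list[int]] = {}
    for cls in present:
        idxs = [
            i for i, c in assignment.column_class.items()
            if c == cls and i != assignment.id_column_index.get(cls)
        ]
        per_class_cols[cls] = sorted(idxs)
        ds.tables[cls] = InstanceTable(
            class_uri=cls,
            table_name=table_name_for_class(cls),
            id_column=(
                table.columns[assignment.id_column_index[cls]].header
                if assignment.has_explicit_id(cls)
                else "localID"
            ),
            explicit=assignment.has_explicit_id(cls),
            literal_columns=[
                Column(table.columns[i].header,
                       assignment.column_term.get(i, table.columns[i].term_uri))
                for i in sorted(idxs)
            ],
        )

    for row in table.rows:
        link: dict[str, object] = {}
        for cls in present:
            it = ds.tables[cls]
            values = tuple(row[i].strip() for i in per_class_cols[cls])
            if it.explicit:
                id_val = row[assignment.id_column_index[cls]].strip()
                if not id_val:
                    if any(values):
                        msg = (
                            f"{it.table_name}: row with literal values but empty "
                            f"{it.id_column}; skipped for this class"
                        )
                        if strict:
                            raise StrictModeError(msg)
                        warnings.warn(msg)
                    link[cls] = None
                    continue
                key: str | tuple = id_val
            else:
                if not any(values):
                    link[cls] = None
                    continue
                key = (_TUPLE_KEY, values)
            if key in it.instances:
                it.duplicate_rows += 1
                if it.explicit and it.instances[key] != values:
                    msg = (
                        f"{it.table_name}: identifier {key!r} seen with differing "
                        f"values; keeping first-seen"
                    )
                    if strict:
                        raise StrictModeError(msg)
                    if key not in it.id_conflicts:
                        it.id_conflicts.append(key)  # type: ignore[arg-type]
                    warnings.warn(msg)
            else:
                it.instances[key] = values
            link[cls] = key
        ds.link_rows.append(link)
    return ds


def assign_local_ids(dataset: NormalizedDataset) -> NormalizedDataset:
    """Fill identifier strings: explicit IDs pass through, classes without
    an ID column get local integers 1..n in first-appearance order."""
    for it in dataset.tables.values():
        if it.explicit:
            it.ids = {key: key for key in it.instances}  # type: ignore[misc]
        else:
            it.ids = {key: str(n) for n, key in enumerate(it.instances, start=1)}
    return dataset


def normalize_table(table: SourceTable, vocab: Vocabulary,
                    *, strict: bool = False) -> NormalizedDataset:
    """detect_classes + normalize + assign_local_ids in one call."""
    assignment = detect_classes(table, vocab)
    ds = normalize(table, assignment, strict=strict)
    ds.hub_class = _pick_hub(ds, None)
    return assign_local_ids(ds)


def _pick_hub(ds: NormalizedDataset, row_type: str | None) -> str | None:
    if row_type and row_type in ds.tables:
        return row_type
    for cls in ds.tables:
        return cls
    return None


def normalize_archive(archive: DwcArchive, vocab: Vocabulary,
                      *, strict: bool = False) -> NormalizedDataset:
    """Normalize a DwC-A: the core table plus extensions joined via coreid.

    Extension tables are normalized independently; their rows are linked to
    the core's hub-class instance (the core row type's class) through the
    archive's coreid join, so relationship triples can span the star schema.
    """
    assignment = detect_classes(archive.core, vocab)
    ds = normalize(archive.core, assignment, strict=strict)
    ds.hub_class = _pick_hub(ds, archive.core_row_type)
    assign_local_ids(ds)

    if not archive.extensions:
        return ds

    # core id value -> hub instance key, for joining extension rows in
    hub_key_of: dict[str, object] = {}
    if ds.hub_class is not None:
        for row, link in zip(archive.core.rows, ds.link_rows):
            cid = row[archive.core_id_index].strip()
            if cid and cid not in hub_key_of and link.get(ds.hub_class) is not None:
                hub_key_of[cid] = link[ds.hub_class]

    for ext, _row_type, coreid_index in archive.extensions:
        try:
            ext_assignment = detect_classes(ext, vocab)
            ext_ds = normalize(ext, ext_assignment, strict=strict)
        except NormalizationError:
            warnings.warn(f"extension {ext.name!r}: no classes detected; skipped")
            continue
        assign_local_ids(ext_ds)
        key_remap: dict[str, dict] = {}
        for cls, it in ext_ds.tables.items():
            if cls not in ds.tables:
                ds.tables[cls] = it
                key_remap[cls] = {k: k for k in it.instances}
            else:
                base = ds.tables[cls]
                remap = {}
                for key, values in it.instances.items():
                    if key in base.instances:
                        base.duplicate_rows += 1
                        remap[key] = key
                    else:
                        base.instances[key] = values
                        remap[key] = key
                ds.tables[cls] = base
                key_remap[cls] = remap
        # renumber merged non-explicit classes and refresh ids
        assign_local_ids(ds)
        for ext_row, link in zip(ext.rows, ext_ds.link_rows):
            entry: dict[str, object] = {
                cls: key_remap[cls].get(key) if key is not None else None
                for cls, key in link.items()
            }
            cid = ext_row[coreid_index].strip()
            if ds.hub_class is not None and cid in hub_key_of:
                entry.setdefault(ds.hub_class, hub_key_of[cid])
            ds.link_rows.append(entry)
        ds.unassigned_columns.extend(ext_ds.unassigned_columns)
    return ds
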