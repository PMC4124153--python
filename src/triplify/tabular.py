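"""Readers for source data: CSV, spreadsheets and Darwin Core Archives.

Everything is read into a uniform rectangular :class:`SourceTable` of text
cells; no type coercion happens at read time.  Readers are registered in a
:class:`ReaderRegistry` keyed by format tag, so additional formats (e.g. a
database-backed reader) can be plugged in without modifying existing code.

A Darwin Core Archive is a zip whose ``meta.xml`` descriptor declares a core
data file (with a row type such as ``dwc:Occurrence``, an id column, and a
term URI per column) and optional extension files joined to the core through
a ``coreid`` column — the star schema of the DwC-A standard.
"""

from __future__ import annotations

import csv
import io
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from lxml import etree

from .errors import ArchiveError, FormatError, ReadError

DWCA_NS = "http://rs.tdwg.org/dwc/text/"


@dataclass(frozen=True)
class Column:
    header: str
    term_uri: str | None = None


@dataclass
class SourceTable:
    """A named rectangular table of text cells."""

    name: str
    columns: list[Column]
    rows: list[tuple[str, ...]]

    def __post_init__(self):
        headers = [c.header for c in self.columns]
        if any(not h for h in headers):
            raise ReadError(f"table {self.name!r} has an empty column header")
        dupes = {h for h in headers if headers.count(h) > 1}
        if dupes:
            raise ReadError(
                f"table {self.name!r} has duplicate column headers: {sorted(dupes)}"
            )
        width = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ReadError(
                    f"table {self.name!r} row {i} has {len(row)} cells, expected {width}"
                )

    @property
    def headers(self) -> list[str]:
        return [c.header for c in self.columns]

    def column_index(self, header: str) -> int:
        try:
            return self.headers.index(header)
        except ValueError:
            raise ReadError(
                f"table {self.name!r} has no column {header!r}"
            ) from None


@dataclass
class DwcArchive:
    core: SourceTable
    core_row_type: str
    core_id_index: int
    extensions: list[tuple[SourceTable, str, int]] = field(default_factory=list)


def _pad_or_reject(rows: Iterable[list[str]], width: int, name: str,
                   strict: bool) -> list[tuple[str, ...]]:
    out = []
    for i, row in enumerate(rows):
        if len(row) < width:
            if strict:
                raise ReadError(f"{name}: row {i} has {len(row)} cells, expected {width}")
            warnings.warn(f"{name}: row {i} padded from {len(row)} to {width} cells")
            row = row + [""] * (width - len(row))
        elif len(row) > width:
            if strict:
                raise ReadError(f"{name}: row {i} has {len(row)} cells, expected {width}")
            warnings.warn(f"{name}: row {i} truncated from {len(row)} to {width} cells")
            row = row[:width]
        out.append(tuple(row))
    return out


def read_csv(path: str | Path, *, delimiter: str = ",", quotechar: str = '"',
             has_header: bool = True, strict: bool = False,
             encoding: str = "utf-8-sig") -> SourceTable:
    """Read an RFC 4180-style delimited text file; first row is the header."""
    path = Path(path)
    with open(path, "r", encoding=encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter, quotechar=quotechar)
        rows = list(reader)
    rows = [r for r in rows if r]  # drop fully empty lines
    if not rows:
        raise ReadError(f"{path.name}: empty input")
    if has_header:
        headers, data = rows[0], rows[1:]
    else:
        headers = [f"col{i + 1}" for i in range(len(rows[0]))]
        data = rows
    columns = [Column(h.strip()) for h in headers]
    table = SourceTable(
        name=path.stem,
        columns=columns,
        rows=[],
    )
    table.rows = _pad_or_reject(data, len(columns), path.name, strict)
    table.__post_init__()
    return table


def _read_xlsx(path: str | Path, *, sheet: str | None = None, **_opts) -> SourceTable:
    from openpyxl import load_workbook

    path = Path(path)
    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    raw = [["" if c is None else str(c) for c in row] for row in ws.iter_rows(values_only=True)]
    wb.close()
    raw = [r for r in raw if any(c.strip() for c in r)]
    if not raw:
        raise ReadError(f"{path.name}: empty input")
    columns = [Column(h.strip()) for h in raw[0]]
    rows = _pad_or_reject([list(r) for r in raw[1:]], len(columns), path.name, False)
    return SourceTable(name=path.stem, columns=columns, rows=rows)


def _read_ods(path: str | Path, *, sheet: str | None = None, **_opts) -> SourceTable:
    # Minimal OpenDocument spreadsheet reader: content.xml table rows/cells,
    # honoring number-columns-repeated. Covers flat data sheets.
    path = Path(path)
    ns = {
        "table": "urn:oasis:names:tc:opendocument:xmlns:table:1.0",
        "text": "urn:oasis:names:tc:opendocument:xmlns:text:1.0",
    }
    try:
        with zipfile.ZipFile(path) as zf:
            content = zf.read("content.xml")
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ReadError(f"{path.name}: not a readable ODS file: {exc}") from exc
    root = etree.fromstring(content)
    tables = root.findall(f".//{{{ns['table']}}}table")
    if not tables:
        raise ReadError(f"{path.name}: no sheets found")
    target = tables[0]
    if sheet:
        for t in tables:
            if t.get(f"{{{ns['table']}}}name") == sheet:
                target = t
                break
        else:
            raise ReadError(f"{path.name}: no sheet named {sheet!r}")
    raw: list[list[str]] = []
    for row in target.findall(f"{{{ns['table']}}}table-row"):
        cells: list[str] = []
        for cell in row.findall(f"{{{ns['table']}}}table-cell"):
            repeat = int(cell.get(f"{{{ns['table']}}}number-columns-repeated", "1"))
            text = "".join(cell.itertext())
            # huge trailing repeats encode empty space; cap them
            if not text.strip() and repeat > 1000:
                repeat = 1
            cells.extend([text] * repeat)
        raw.append(cells)
    raw = [r for r in raw if any(c.strip() for c in r)]
    if not raw:
        raise ReadError(f"{path.name}: empty input")
    width = len(raw[0])
    columns = [Column(h.strip()) for h in raw[0]]
    rows = _pad_or_reject(raw[1:], width, path.name, False)
    return SourceTable(name=path.stem, columns=columns, rows=rows)


# -- Darwin Core Archives --------------------------------------------------

_ESCAPES = {"\\t": "\t", "\\n": "\n", "\\r": "\r", "\\r\\n": "\r\n"}


def _unescape(value: str | None, default: str) -> str:
    if value is None:
        return default
    return _ESCAPES.get(value, value)


def _parse_file_element(elem, zf: zipfile.ZipFile, kind: str):
    ns = f"{{{DWCA_NS}}}"
    row_type = elem.get("rowType")
    if not row_type:
        raise ArchiveError(f"{kind} element lacks a rowType attribute")
    loc = elem.find(f"{ns}files/{ns}location")
    if loc is None or not loc.text:
        raise ArchiveError(f"{kind} element lacks a file location")
    filename = loc.text.strip()
    if filename not in zf.namelist():
        raise ArchiveError(f"data file {filename!r} referenced in meta.xml is missing")
    delim = _unescape(elem.get("fieldsTerminatedBy"), ",")
    quote = elem.get("fieldsEnclosedBy")
    quote = quote if quote else None
    ignore = int(elem.get("ignoreHeaderLines", "0"))
    encoding = elem.get("encoding", "UTF-8")

    fields = {}
    for f in elem.findall(f"{ns}field"):
        idx = int(f.get("index"))
        fields[idx] = f.get("term")
    id_elem = elem.find(f"{ns}id") if kind == "core" else elem.find(f"{ns}coreid")
    id_index = int(id_elem.get("index")) if id_elem is not None else None

    text = zf.read(filename).decode(encoding)
    if quote:
        reader = csv.reader(io.StringIO(text, newline=""), delimiter=delim,
                            quotechar=quote)
        raw = [row for row in reader]
    else:
        raw = [line.split(delim) for line in text.splitlines()]
    raw = [r for r in raw if any(c.strip() for c in r)]
    header_rows, data = raw[:ignore], raw[ignore:]

    max_idx = max([*fields.keys(), id_index if id_index is not None else 0], default=0)
    width = max_idx + 1
    for idx in fields:
        if idx < 0:
            raise ArchiveError(f"field index {idx} out of range in {filename!r}")
    if data:
        actual_width = max(len(r) for r in data)
        if max_idx >= actual_width:
            raise ArchiveError(
                f"field index {max_idx} out of range for {filename!r} "
                f"({actual_width} columns)"
            )
        width = max(width, actual_width)

    from .vocabulary import split_uri

    columns = []
    used = set()
    for i in range(width):
        term = fields.get(i)
        if term:
            try:
                _, local = split_uri(term)
            except Exception:
                local = term.rsplit("/", 1)[-1]
            header = local
        elif i == id_index:
            header = "id"
        else:
            header = f"col{i + 1}"
        if header_rows and i < len(header_rows[0]) and header_rows[0][i].strip():
            # keep the file's own header when it exists and is unique
            file_header = header_rows[0][i].strip()
            if term is None:
                header = file_header
        while header in used:
            header = header + "_"
        used.add(header)
        columns.append(Column(header, term))
    rows = _pad_or_reject(data, width, filename, False)
    table = SourceTable(name=Path(filename).stem, columns=columns, rows=rows)
    return table, row_type, id_index


def read_dwca(path: str | Path) -> DwcArchive:
    """Read a Darwin Core Archive (zip with a ``meta.xml`` descriptor)."""
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"{path.name}: not a zip archive") from exc
    with zf:
        meta_name = next((n for n in zf.namelist()
                          if n == "meta.xml" or n.endswith("/meta.xml")), None)
        if meta_name is None:
            raise ArchiveError(f"{path.name}: no meta.xml — not a Darwin Core Archive")
        try:
            root = etree.fromstring(zf.read(meta_name))
        except etree.XMLSyntaxError as exc:
            raise ArchiveError(f"{path.name}: malformed meta.xml: {exc}") from exc
        ns = f"{{{DWCA_NS}}}"
        core_elem = root.find(f"{ns}core")
        if core_elem is None:
            raise ArchiveError(f"{path.name}: meta.xml has no <core> element")
        core, core_row_type, core_id_index = _parse_file_element(core_elem, zf, "core")
        if core_id_index is None:
            core_id_index = 0
        extensions = []
        for ext_elem in root.findall(f"{ns}extension"):
            ext, row_type, coreid_index = _parse_file_element(ext_elem, zf, "extension")
            if coreid_index is None:
                raise ArchiveError(
                    f"{path.name}: extension {ext.name!r} lacks a <coreid> element"
                )
            extensions.append((ext, row_type, coreid_index))

    core_ids = {r[core_id_index] for r in core.rows}
    for ext, row_type, coreid_index in extensions:
        orphans = [r[coreid_index] for r in ext.rows if r[coreid_index] not in core_ids]
        if orphans:
            warnings.warn(
                f"extension {ext.name!r}: {len(orphans)} rows reference unknown core ids"
            )
    return DwcArchive(core, core_row_type, core_id_index, extensions)


# -- format detection and the reader registry ------------------------------

def detect_format(path: str | Path) -> str:
    """Classify an input file as one of ``csv``, ``xlsx``, ``ods``, ``dwca``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    suffix = path.suffix.lower()
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
        if any(n == "meta.xml" or n.endswith("/meta.xml") for n in names):
            return "dwca"
        if suffix == ".xlsx":
            return "xlsx"
        if suffix == ".ods" or "content.xml" in names:
            return "ods"
        raise FormatError(
            f"{path.name}: zip without meta.xml; supported formats: csv, txt, xlsx, ods, dwca"
        )
    if suffix in {".csv", ".txt", ".tsv"}:
        return "csv"
    raise FormatError(
        f"{path.name}: unsupported format {suffix!r}; supported: csv, txt, xlsx, ods, dwca (zip)"
    )


class ReaderRegistry:
    """Format tag -> reader callable (path, **options) -> SourceTable|DwcArchive."""

    def __init__(self):
        self._readers: dict[str, Callable] = {}

    def register(self, tag: str, reader: Callable) -> None:
        self._readers[tag] = reader

    def get(self, tag: str) -> Callable:
        try:
            return self._readers[tag]
        except KeyError:
            raise FormatError(
                f"no reader for format {tag!r}; available: {sorted(self._readers)}"
            ) from None

    def read(self, path: str | Path, tag: str | None = None, **options):
        tag = tag or detect_format(path)
        return self.get(tag)(path, **options)


DEFAULT_REGISTRY = ReaderRegistry()
DEFAULT_REGISTRY.register("csv", read_csv)
DEFAULT_REGISTRY.register("xlsx", _read_xlsx)
DEFAULT_REGISTRY.register("ods", _read_ods)
DEFAULT_REGISTRY.register("dwca", read_dwca)
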