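"""Readers: CSV, spreadsheets, DwC-A zips, and format detection."""

import zipfile

import pytest

from triplify import detect_format, generate_dwca, read_csv, read_dwca
from triplify.errors import ArchiveError, FormatError, ReadError
from triplify.fixtures import FixtureSpec, OCCURRENCE, TAXON
from triplify.tabular import DEFAULT_REGISTRY

DWC = "http://rs.tdwg.org/dwc/terms/"


class TestCsv:
    def test_header_plus_rows(self, tmp_path):
        p = tmp_path / "data.csv"
        p.write_text("occurrenceID,scientificName\nOCC1,Quercus alba\nOCC2,Acer rubrum\n")
        table = read_csv(p)
        assert table.name == "data"
        assert table.headers == ["occurrenceID", "scientificName"]
        assert table.rows == [("OCC1", "Quercus alba"), ("OCC2", "Acer rubrum")]

    def test_quoted_comma_per_rfc4180(self, tmp_path):
        p = tmp_path / "q.csv"
        p.write_text('locality,country\n"Creek, upper fork",US\n')
        table = read_csv(p)
        assert table.rows == [("Creek, upper fork", "US")]

    def test_duplicate_headers_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("taxonID,taxonID\n1,2\n")
        with pytest.raises(ReadError, match="taxonID"):
            read_csv(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ReadError, match="empty"):
            read_csv(p)

    def test_ragged_rows_padded_with_warning(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("a,b,c\n1,2\n")
        with pytest.warns(UserWarning, match="padded"):
            table = read_csv(p)
        assert table.rows == [("1", "2", "")]

    def test_ragged_rows_rejected_in_strict_mode(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("a,b,c\n1,2\n")
        with pytest.raises(ReadError):
            read_csv(p, strict=True)

    def test_utf8_bom_tolerated(self, tmp_path):
        p = tmp_path / "bom.csv"
        p.write_bytes("﻿a,b\n1,2\n".encode("utf-8"))
        assert read_csv(p).headers == ["a", "b"]

    def test_cells_preserved_losslessly(self, tmp_path):
        cells = ["x", "héllo", 'say "hi"', "a,b", "1.5"]
        p = tmp_path / "l.csv"
        body = ",".join(
            '"' + c.replace('"', '""') + '"' for c in cells
        )
        p.write_text("c1,c2,c3,c4,c5\n" + body + "\n", encoding="utf-8")
        table = read_csv(p)
        assert sorted(table.rows[0]) == sorted(cells)


class TestSpreadsheets:
    def test_xlsx_roundtrip(self, tmp_path):
        openpyxl = pytest.importorskip("openpyxl")
        p = tmp_path / "book.xlsx"
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(["occurrenceID", "scientificName"])
        ws.append(["OCC1", "Quercus alba"])
        wb.save(p)
        table = DEFAULT_REGISTRY.read(p, "xlsx")
        assert table.headers == ["occurrenceID", "scientificName"]
        assert table.rows == [("OCC1", "Quercus alba")]

    def test_ods_flat_sheet(self, tmp_path):
        content = """<?xml version="1.0" encoding="UTF-8"?>
<office:document-content
 xmlns:office="urn:oasis:names:tc:opendocument:xmlns:office:1.0"
 xmlns:table="urn:oasis:names:tc:opendocument:xmlns:table:1.0"
 xmlns:text="urn:oasis:names:tc:opendocument:xmlns:text:1.0">
 <office:body><office:spreadsheet>
  <table:table table:name="Sheet1">
   <table:table-row>
    <table:table-cell><text:p>occurrenceID</text:p></table:table-cell>
    <table:table-cell><text:p>locality</text:p></table:table-cell>
   </table:table-row>
   <table:table-row>
    <table:table-cell><text:p>OCC1</text:p></table:table-cell>
    <table:table-cell><text:p>Sagehen Creek</text:p></table:table-cell>
   </table:table-row>
  </table:table>
 </office:spreadsheet></office:body>
</office:document-content>"""
        p = tmp_path / "book.ods"
        with zipfile.ZipFile(p, "w") as zf:
            zf.writestr("mimetype", "application/vnd.oasis.opendocument.spreadsheet")
            zf.writestr("content.xml", content)
        table = DEFAULT_REGISTRY.read(p, "ods")
        assert table.headers == ["occurrenceID", "locality"]
        assert table.rows == [("OCC1", "Sagehen Creek")]


def make_archive(path, meta, files):
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.xml", meta)
        for name, text in files.items():
            zf.writestr(name, text)
    return path


META_TABBED = f"""<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core encoding="UTF-8" fieldsTerminatedBy="\\t" linesTerminatedBy="\\n"
        ignoreHeaderLines="1" rowType="{DWC}Occurrence">
    <files><location>occ.txt</location></files>
    <id index="0"/>
    <field index="0" term="{DWC}occurrenceID"/>
    <field index="1" term="{DWC}scientificName"/>
    <field index="2" term="{DWC}eventDate"/>
  </core>
</archive>
"""


class TestDwca:
    def test_generated_archive_reads_back(self, tmp_path):
        spec = FixtureSpec(n_rows=5, classes=(OCCURRENCE, TAXON), seed=1)
        generate_dwca(spec, tmp_path / "a.zip")
        archive = read_dwca(tmp_path / "a.zip")
        assert archive.core_row_type == DWC + "Occurrence"
        assert archive.core_id_index == 0
        assert len(archive.core.rows) == 5
        assert archive.core.columns[0].term_uri == DWC + "occurrenceID"
        terms = [c.term_uri for c in archive.core.columns]
        assert DWC + "scientificName" in terms

    def test_declared_tab_delimiter_is_applied(self, tmp_path):
        data = "id\tname\tdate\nOCC1\tQuercus alba, white oak\t1998-04-12\n"
        p = make_archive(tmp_path / "t.zip", META_TABBED, {"occ.txt": data})
        archive = read_dwca(p)
        assert archive.core.rows == [("OCC1", "Quercus alba, white oak", "1998-04-12")]

    def test_zip_without_meta_xml_is_not_a_dwca(self, tmp_path):
        p = tmp_path / "plain.zip"
        with zipfile.ZipFile(p, "w") as zf:
            zf.writestr("data.csv", "a,b\n1,2\n")
        with pytest.raises(ArchiveError, match="meta.xml"):
            read_dwca(p)

    def test_field_index_out_of_range_is_a_descriptor_error(self, tmp_path):
        meta = META_TABBED.replace('index="2"', 'index="9"')
        p = make_archive(tmp_path / "bad.zip", meta,
                         {"occ.txt": "id\tname\tdate\nOCC1\tx\ty\n"})
        with pytest.raises(ArchiveError, match="out of range"):
            read_dwca(p)

    def test_missing_data_file_is_an_archive_error(self, tmp_path):
        p = make_archive(tmp_path / "m.zip", META_TABBED, {})
        with pytest.raises(ArchiveError, match="missing"):
            read_dwca(p)

    def test_extension_rows_join_core_ids_and_orphans_warn(self, tmp_path):
        meta = f"""<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core fieldsTerminatedBy="," ignoreHeaderLines="1" rowType="{DWC}Occurrence">
    <files><location>occ.csv</location></files>
    <id index="0"/>
    <field index="0" term="{DWC}occurrenceID"/>
  </core>
  <extension fieldsTerminatedBy="," ignoreHeaderLines="1" rowType="{DWC}Identification">
    <files><location>ident.csv</location></files>
    <coreid index="0"/>
    <field index="1" term="{DWC}identifiedBy"/>
  </extension>
</archive>
"""
        p = make_archive(tmp_path / "ext.zip", meta, {
            "occ.csv": "id\nOCC1\nOCC2\n",
            "ident.csv": "coreid,who\nOCC1,E. Mayr\nOCC9,R. Fisher\n",
        })
        with pytest.warns(UserWarning, match="unknown core ids"):
            archive = read_dwca(p)
        assert len(archive.extensions) == 1
        ext, row_type, coreid_index = archive.extensions[0]
        assert row_type == DWC + "Identification"
        assert coreid_index == 0
        assert len(ext.rows) == 2


class TestDetectFormat:
    def test_dwca_by_content(self, tmp_path):
        spec = FixtureSpec(n_rows=1, seed=0)
        generate_dwca(spec, tmp_path / "occ.zip")
        assert detect_format(tmp_path / "occ.zip") == "dwca"

    @pytest.mark.parametrize("name, tag", [("d.csv", "csv"), ("d.txt", "csv")])
    def test_delimited_text(self, tmp_path, name, tag):
        p = tmp_path / name
        p.write_text("a,b\n1,2\n")
        assert detect_format(p) == tag

    def test_unsupported_format_lists_alternatives(self, tmp_path):
        p = tmp_path / "notes.pdf"
        p.write_bytes(b"%PDF-1.4")
        with pytest.raises(FormatError, match="csv"):
            detect_format(p)

    def test_readers_are_deterministic(self, tmp_path):
        spec = FixtureSpec(n_rows=10, seed=3)
        generate_dwca(spec, tmp_path / "occ.zip")
        a = read_dwca(tmp_path / "occ.zip")
        b = read_dwca(tmp_path / "occ.zip")
        assert a.core.rows == b.core.rows
        assert a.core.headers == b.core.headers
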