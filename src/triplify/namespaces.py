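"""Shared URI prefixes used throughout the package.

These are the short-form prefixes conventional in Darwin Core linked-data
work: ``dwc`` for the TDWG Darwin Core terms, ``dcterms`` for Dublin Core,
``bsc`` for the BiSciCol relationship vocabulary, and ``ro`` for the OBO
Relation Ontology (only ``derives_from`` is used from it).
"""

from rdflib import Namespace
from rdflib.namespace import OWL, RDF, RDFS

BSC = Namespace("http://biscicol.org/terms/biscicol.owl#")
DCTERMS = Namespace("http://purl.org/dc/terms/")
DWC = Namespace("http://rs.tdwg.org/dwc/terms/")
DWCATTRIBUTES = Namespace("http://rs.tdwg.org/dwc/terms/attributes/")
RO = Namespace("http://www.obofoundry.org/ro/ro.owl#")

#: prefix -> namespace URI, in the order they are bound on output graphs
PREFIXES = {
    "bsc": str(BSC),
    "dcterms": str(DCTERMS),
    "dwc": str(DWC),
    "dwcattributes": str(DWCATTRIBUTES),
    "owl": str(OWL),
    "rdf": str(RDF),
    "ro": str(RO),
}

__all__ = ["BSC", "DCTERMS", "DWC", "DWCATTRIBUTES", "RO", "OWL", "RDF", "RDFS", "PREFIXES"]
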