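[
  {
    "subject_class": "http://rs.tdwg.org/dwc/terms/Occurrence",
    "property": "http://biscicol.org/terms/biscicol.owl#related_to",
    "object_class": "http://rs.tdwg.org/dwc/terms/Taxon"
  },
  {
    "subject_class": "http://rs.tdwg.org/dwc/terms/Identification",
    "property": "http://biscicol.org/terms/biscicol.owl#depends_on",
    "object_class": "http://rs.tdwg.org/dwc/terms/Occurrence"
  },
  {
    "subject_class": "http://rs.tdwg.org/dwc/terms/Identification",
    "property": "http://biscicol.org/terms/biscicol.owl#related_to",
    "object_class": "http://rs.tdwg.org/dwc/terms/Taxon"
  },
  {
    "subject_class": "http://rs.tdwg.org/dwc/terms/Occurrence",
    "property": "http://biscicol.org/terms/biscicol.owl#depends_on",
    "object_class": "http://rs.tdwg.org/dwc/terms/Event"
  },
  {
    "subject_class": "http://rs.tdwg.org/dwc/terms/Event",
    "property": "http://biscicol.org/terms/biscicol.owl#related_to",
    "object_class": "http://purl.org/dc/terms/Location"
  },
  {
    "subject_class": "http://rs.tdwg.org/dwc/terms/Event",
    "property": "http://biscicol.org/terms/biscicol.owl#related_to",
    "object_class": "http://rs.tdwg.org/dwc/terms/GeologicalContext"
  }
]
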