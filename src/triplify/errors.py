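"""Exception hierarchy for the conversion pipeline."""


class TriplifyError(Exception):
    """Base class for all errors raised by this package."""


class VocabularyError(TriplifyError):
    """Malformed vocabulary snapshot or unresolvable term lookup."""


class AmbiguousTermError(VocabularyError):
    """A bare column name matched terms in more than one prefix."""

    def __init__(self, name: str, candidates):
        self.name = name
        self.candidates = list(candidates)
        super().__init__(
            f"column name {name!r} is ambiguous; candidates: "
            + ", ".join(sorted(self.candidates))
        )


class UnknownPropertyError(TriplifyError):
    """A URI that is not one of the four relationship properties."""


class OntologyConfigError(TriplifyError):
    """Inconsistent class-graph configuration (e.g. duplicate pair edges)."""


class FormatError(TriplifyError):
    """Unsupported or unrecognizable input format."""


class ReadError(TriplifyError):
    """A source file violates the rectangular-table contract."""


class ArchiveError(ReadError):
    """A Darwin Core Archive is structurally invalid."""


class NormalizationError(TriplifyError):
    """The table cannot be split into per-class instance tables."""


class MappingError(TriplifyError):
    """Invalid mapping configuration or mapping file."""


class AutoMappingError(MappingError):
    """No classes detectable, so a mapping cannot be built automatically."""


class IdentifierError(TriplifyError):
    """Instance identifier cannot be turned into an IRI."""


class EmissionError(TriplifyError):
    """Triple emission failed (e.g. a join column disappeared)."""


class StrictModeError(TriplifyError):
    """A warning promoted to an error under --strict."""
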