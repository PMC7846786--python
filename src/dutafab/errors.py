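"""Exception hierarchy shared across the toolkit."""


class DutafabError(Exception):
    """Base class for all toolkit errors."""


class FastaError(DutafabError):
    """Malformed FASTA input or chain-pairing problem."""


class NumberingError(DutafabError):
    """Sequence cannot be numbered on the embedded templates."""


class SchemeError(DutafabError):
    """Unknown or inconsistent CDR scheme / paratope definition."""


class MergeError(DutafabError):
    """Paratope merging violated its contract (off-paratope deviation, conflict)."""


class MutationError(DutafabError):
    """A point-mutation spec does not apply to the sequence."""


class LibraryError(DutafabError):
    """Library specification violates scaffold rules or side ownership."""


class StructureError(DutafabError):
    """Structure I/O or geometry problem."""
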