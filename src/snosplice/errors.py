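"""Exception hierarchy.

``DataError`` subtypes map to CLI exit status 2 (malformed or inconsistent
input data); anything else is a programming error and propagates.
"""


class DataError(Exception):
    """Malformed or inconsistent input data."""


class AnnotationError(DataError):
    """Problem in a GFF3/FASTA annotation set (bad coordinates, orphans...)."""


class FoldInputError(DataError):
    """Sequence handed to the folding engine is not plain A/C/G/U RNA."""


class AlignmentError(DataError):
    """Homolog alignment inconsistent with the reference structure."""


class SimulationError(DataError):
    """Infeasible synthetic locus specification."""
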