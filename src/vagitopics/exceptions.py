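"""Exception hierarchy for vagitopics."""


class VagitopicsError(Exception):
    """Base class for all package errors."""


class FormatError(VagitopicsError):
    """A file or lineage string does not follow the expected dialect."""


class ValidationError(VagitopicsError):
    """Input data violate a structural invariant (duplicates, mismatched ids...)."""


class EmptyResultError(VagitopicsError):
    """A filtering step removed everything."""


class SeparationError(VagitopicsError):
    """A logistic design is perfectly (quasi-)separated."""
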