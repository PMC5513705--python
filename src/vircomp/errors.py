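"""Exception hierarchy shared across vircomp modules."""


class VircompError(Exception):
    """Base class for all vircomp errors."""


class ParameterError(VircompError, ValueError):
    """Invalid generator or analysis parameter; message names the field."""


class EmptySampleError(VircompError, ValueError):
    """An operation that needs at least one read received none."""


class InsufficientReadsError(VircompError, ValueError):
    """An estimator that needs N >= 2 reads received fewer."""


class DepthError(VircompError, ValueError):
    """Requested rarefaction depth exceeds the sample's read count."""


class LookupError_(VircompError, KeyError):
    """A required taxonomy or vocabulary entry is missing; message names it."""


class SchemaError(VircompError, ValueError):
    """A tabular input violates its schema (missing column, bad type)."""


class PathwayValidationError(VircompError, ValueError):
    """A pathway database violates a structural invariant."""


class FormatError(VircompError, ValueError):
    """A field (e.g. an EC number) does not match its required format."""
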