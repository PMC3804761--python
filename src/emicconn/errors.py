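"""Typed errors shared across the package."""


class EmicConnError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(EmicConnError, ValueError):
    """A vector has zero variance (or is otherwise uninformative).

    Association measures refuse such input instead of silently returning 0;
    the connectivity layer decides how to map it onto an edge value.
    """


class SearchBudgetError(EmicConnError, ValueError):
    """A requested grid search exceeds the configured budget."""


class ManifestError(EmicConnError, ValueError):
    """A cohort manifest or input file is malformed."""
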