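"""Exception hierarchy shared across the pipeline."""


class PsiScreenError(Exception):
    """Base class for all package errors."""


class FormatError(PsiScreenError, ValueError):
    """A file or in-memory structure violates the documented dialect."""


class ConsistencyError(PsiScreenError, ValueError):
    """Cross-references between inputs disagree (e.g. unknown subject id)."""


class DegenerateInputError(PsiScreenError, ValueError):
    """Numerically degenerate input (zero spectrum, singular covariance...)."""
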