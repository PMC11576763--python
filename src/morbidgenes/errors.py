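"""Exception hierarchy shared across the package.

Two failure classes matter to callers: a file that does not follow its
declared dialect (:class:`FormatError`) and data that parses but violates a
structural invariant such as a duplicate accession (:class:`IntegrityError`).
The CLI maps them to distinct exit codes.
"""


class MorbidGenesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MorbidGenesError):
    """A snapshot or panel file does not match its documented dialect."""


class IntegrityError(MorbidGenesError):
    """Parsed data violates a structural invariant (e.g. duplicate key)."""
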