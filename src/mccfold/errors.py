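"""Exception taxonomy shared across the package."""


class MccfoldError(Exception):
    """Base class for all package errors."""


class FormatError(MccfoldError):
    """A file or text payload violates its interchange format."""


class ValidityError(MccfoldError):
    """A structure matrix or pair map violates the validity constraints."""


class ContractError(MccfoldError):
    """An operation was called with arguments violating its preconditions."""


class ConfigError(MccfoldError):
    """A model or run configuration is internally inconsistent."""


class TeacherError(MccfoldError):
    """An external teacher executable failed or produced unparseable output."""
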