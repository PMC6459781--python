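"""Exception hierarchy shared across the package."""


class NbdaCutoffError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(NbdaCutoffError):
    """A file or cell does not conform to the expected dialect."""


class ValidationError(NbdaCutoffError):
    """An in-memory object violates a structural invariant."""


class ConfigError(NbdaCutoffError):
    """A configuration object is internally inconsistent or infeasible."""


class DegenerateFitError(NbdaCutoffError):
    """Too few acquisition events remain for the OADA fit to be meaningful."""


class DegenerateCutoffError(NbdaCutoffError):
    """A cut-off removed so many individuals that no analysis is possible."""
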