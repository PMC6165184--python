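"""Exception hierarchy for mrkit.

All package errors derive from :class:`MrKitError` so callers can catch one
base class; subclasses distinguish configuration mistakes from bad data rows,
harmonization failures and estimator preconditions.
"""


class MrKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigError(MrKitError):
    """A configuration problem detected before any data is touched
    (missing column mapping, invalid threshold, unknown method name)."""


class SummaryTableError(MrKitError):
    """One or more data rows of a summary-statistics table are invalid.

    Carries ``row_errors``, a list of ``(line_number, message)`` pairs
    (line numbers refer to the physical file, header = line 1).
    """

    def __init__(self, path, row_errors):
        self.path = path
        self.row_errors = list(row_errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors)
        super().__init__(f"{path}: {lines}")


class ValidationError(MrKitError):
    """A domain-type invariant was violated (duplicate rsid, se <= 0, ...)."""


class ProxyError(MrKitError):
    """Proxy substitution refused or impossible (low r2, missing proxy)."""


class HarmonizationError(MrKitError):
    """Exposure/outcome records cannot be aligned to a common allele."""


class EstimationError(MrKitError):
    """An estimator precondition failed (too few instruments, zero
    exposure effect, degenerate weights)."""
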