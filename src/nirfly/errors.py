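"""Exception hierarchy.

All errors raised by this package derive from :class:`NirflyError`, so callers
can catch one base class.  Validation problems (bad grids, inconsistent
metadata) and format problems (unreadable files) are distinguished because
the former usually indicate a science mistake and the latter a plumbing one.
"""


class NirflyError(Exception):
    """Base class for all package errors."""


class SpectraFormatError(NirflyError):
    """A spectra or metadata file could not be parsed."""


class ValidationError(NirflyError):
    """Data violate an invariant (grid, units, metadata consistency)."""


class ConfigError(NirflyError):
    """A configuration value is out of range or internally inconsistent."""


class DesignError(NirflyError):
    """A study design precondition fails (e.g. single-class calibration)."""
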