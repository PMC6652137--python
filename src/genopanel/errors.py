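"""Exception hierarchy shared across the package.

Each error class carries a short machine-parseable ``category`` and a
dedicated CLI exit code so scripted callers can branch on failures.
"""

from __future__ import annotations


class GenoPanelError(Exception):
    """Base class for all package errors."""

    category = "error"
    exit_code = 1


class ParameterError(GenoPanelError):
    """A user-supplied parameter is out of its documented bounds."""

    category = "parameter-error"
    exit_code = 3


class InputFormatError(GenoPanelError):
    """An input file violates its format contract (VCF/TSV/labels)."""

    category = "input-format-error"
    exit_code = 4


class PanelVersionError(GenoPanelError):
    """A serialized panel was written by an incompatible format version."""

    category = "panel-version-error"
    exit_code = 5


class IncompatibilityError(GenoPanelError):
    """Panel and query/table do not share a usable site index."""

    category = "incompatibility-error"
    exit_code = 6


class EmptyPanelError(GenoPanelError):
    """Filtering removed every site; no panel can be built."""

    category = "empty-panel-error"
    exit_code = 7
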