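"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2 (click's own
convention), :class:`DataValidationError` exits 3 and :class:`SolverError`
exits 4.
"""


class PpisparseError(Exception):
    """Base class for all package-specific errors."""


class ProfileError(PpisparseError, ValueError):
    """Invalid reduced-alphabet cluster profile specification."""


class SequenceError(PpisparseError, ValueError):
    """A residue sequence cannot be mapped or is too short."""


class DataValidationError(PpisparseError, ValueError):
    """Malformed input files: FASTA, pair lists, feature matrices."""


class ParameterError(PpisparseError, ValueError):
    """Out-of-range model parameter (e.g. non-positive sigma or epsilon)."""


class SolverError(PpisparseError, RuntimeError):
    """The l1 solver failed to produce a feasible coefficient vector."""
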