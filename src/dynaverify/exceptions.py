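"""Exception hierarchy for dynaverify.

All library errors derive from :class:`DynaverifyError` so callers (and the
CLI) can catch one base class and map it to a nonzero exit code.
"""


class DynaverifyError(Exception):
    """Base class for all dynaverify errors."""


class DynalogParseError(DynaverifyError):
    """A dynalog bank file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DynalogStructureError(DynaverifyError):
    """Parsed records violate a structural invariant (e.g. leaf count drift)."""


class MergeError(DynaverifyError):
    """The A/B bank pair cannot be merged (count mismatch, truncated file)."""


class ConsistencyError(DynaverifyError):
    """Shared per-record scalars of the two banks disagree beyond tolerance."""


class ReconstructionError(DynaverifyError):
    """Record selection produced fewer than two usable control points."""


class MagnificationError(DynaverifyError):
    """Leaf errors cannot be magnified (maximum leaf error at/below floor)."""


class UnsupportedPlanError(DynaverifyError):
    """The DICOM RTPLAN lacks the dynamic-MLC structure this tool needs."""


class DoseComparisonError(DynaverifyError):
    """A dose/DVH comparison is undefined for the given inputs."""


class UncertaintyRequiredError(DoseComparisonError):
    """Systematic-difference analysis needs per-voxel statistical uncertainty."""
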