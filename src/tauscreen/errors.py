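"""Exception types shared across the pipeline."""


class TauscreenError(Exception):
    """Base class for all package errors."""


class IncompleteFieldError(TauscreenError):
    """A field image is missing one or more required channels ("incomplete field")."""


class ChannelGeometryError(TauscreenError):
    """Channel grids of one field do not share a shape ("channel geometry mismatch")."""


class DuplicateWellError(TauscreenError):
    """A plate map lists the same well twice ("duplicate well")."""


class NoNegativeControlError(TauscreenError):
    """A plate map contains no DMSO well ("no negative control")."""


class LabelOverflowError(TauscreenError):
    """A label mask holds more labels than fit in 16 bits ("label overflow")."""


class MaskGeometryError(TauscreenError):
    """Component masks are not on one pixel grid ("mask geometry mismatch")."""


class UnmappedTreatmentError(TauscreenError):
    """A compound well has no simulated effect entry ("unmapped treatment")."""


class MissingControlError(TauscreenError):
    """A plate lacks the control group needed for a QC computation ("missing control")."""


class InsufficientFieldsError(TauscreenError):
    """Fewer than two values available for a confidence bound ("insufficient fields")."""


class InvalidReferenceError(TauscreenError):
    """Normalisation reference is empty, zero or undefined ("invalid reference")."""


class ZeroDynamicRangeError(TauscreenError):
    """Control groups have equal means; z-factor undefined ("zero dynamic range")."""


class NoDoseDependenceError(TauscreenError):
    """Responses are flat across doses; a 4PL fit is meaningless ("no dose dependence")."""
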