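"""Exception hierarchy for painttools."""


class PaintToolsError(Exception):
    """Base class for all package errors."""


class InvalidAlphabetError(PaintToolsError, ValueError):
    """Sequence contains a non-nucleotide character (position reported)."""


class SequenceTooShortError(PaintToolsError, ValueError):
    """Sequence is shorter than the operation requires."""


class UnsupportedConditionError(PaintToolsError, ValueError):
    """Hybridization conditions outside the supported regime (e.g. Na = 0)."""


class MaskError(PaintToolsError, ValueError):
    """LNA mask index out of range or malformed."""


class NoCandidatesError(PaintToolsError, ValueError):
    """Candidate stream for shortlisting was empty."""


class UnknownDockingError(PaintToolsError, KeyError):
    """Docking-strand id not present in the configured library."""


class ParameterError(PaintToolsError, ValueError):
    """Invalid numeric parameter (rate, concentration, count ...)."""


class InsufficientDataError(PaintToolsError, ValueError):
    """Too few observations for the requested estimator.

    Carries ``n_available`` and ``n_required``.
    """

    def __init__(self, message: str, n_available: int, n_required: int):
        super().__init__(message)
        self.n_available = n_available
        self.n_required = n_required


class InsufficientFiducialsError(PaintToolsError, ValueError):
    """No fiducial track covers enough of the acquisition for drift correction."""


class RegistrationError(PaintToolsError, ValueError):
    """Too few matched fiducial pairs for channel registration."""


class InsufficientPointsError(PaintToolsError, ValueError):
    """A localization channel has too few points for colocalization scoring."""


class LayoutError(PaintToolsError, ValueError):
    """Simulated regions overlap or are otherwise geometrically invalid."""
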