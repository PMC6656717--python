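"""Exception types shared across the pipeline."""


class WlscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(WlscoreError):
    """Input table or value failed validation; message names the offending record."""


class FitError(WlscoreError):
    """A statistical model could not be fitted (rank deficiency, one-class outcome...)."""


class SeparationError(FitError):
    """Logistic fit hit complete or quasi-complete separation; flagged, never silent."""


class DegenerateDataError(WlscoreError):
    """Computation undefined on this input (constant scores, zero-margin table...)."""
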