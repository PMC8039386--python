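"""Exception types shared across the pipeline stages."""


class GastrolayerError(Exception):
    """Base class for all package-specific errors."""


class LayerTooThinError(GastrolayerError):
    """A requested layer rounds to zero pixels in the phantom template."""


class CannotStratifyError(GastrolayerError):
    """Fewer than four interior edges were found in a column profile.

    Carries ``n_found``, the number of usable interior gradient peaks, so
    callers can log why an image fails the "can be divided into five
    layers" gate.
    """

    def __init__(self, n_found: int, message: str | None = None):
        self.n_found = n_found
        super().__init__(message or f"cannot stratify: found {n_found} interior edges, need 4")


class UnstratifiableROIError(GastrolayerError):
    """Too few columns of an ROI could be stratified.

    ``diagnostics`` maps column index -> number of interior edges found
    (or "ok" for columns that succeeded).
    """

    def __init__(self, diagnostics: dict, min_valid: int):
        self.diagnostics = diagnostics
        self.min_valid = min_valid
        n_ok = sum(1 for v in diagnostics.values() if v == "ok")
        super().__init__(
            f"unstratifiable ROI: {n_ok} columns stratified, need at least {min_valid}"
        )


class NoWallDetectedError(GastrolayerError):
    """An empty mask was passed where a wall region is required."""
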