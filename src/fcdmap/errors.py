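"""Exception hierarchy for the FCD mapping pipeline."""


class FCDError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FCDError):
    """A parameter or configuration value is invalid (e.g. a band edge at
    or above Nyquist, a phantom network that does not fit the grid)."""


class InputError(FCDError):
    """An input array or table violates a precondition (wrong shape,
    too short, missing column)."""


class ZeroVarianceError(InputError):
    """A voxel time series is constant where nonzero variance is required.

    Carries the flat voxel indices in ``voxels`` so callers can report or
    re-mask them.
    """

    def __init__(self, voxels, message=None):
        self.voxels = list(voxels)
        if message is None:
            message = (
                f"{len(self.voxels)} zero-variance voxel(s) in the working "
                f"mask (first few: {self.voxels[:5]}); remove them from the "
                "mask before computing correlations"
            )
        super().__init__(message)


class RankDeficiencyError(InputError):
    """A regression design matrix is rank deficient.

    ``columns`` names the offending (collinear) columns.
    """

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        if message is None:
            message = (
                "design matrix is rank deficient; collinear column(s): "
                + ", ".join(map(str, self.columns))
            )
        super().__init__(message)


class InternalConsistencyError(FCDError):
    """Two quantities that must agree by construction do not
    (e.g. a contralateral count exceeding the global count)."""
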