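"""Exception hierarchy for burstfish."""


class BurstfishError(Exception):
    """Base class for all package errors."""


class ParameterError(BurstfishError, ValueError):
    """A parameter lies outside its mathematical domain."""


class DataError(BurstfishError, ValueError):
    """Malformed or empty input data (bad CSV header, non-integer counts, ...)."""


class FitError(BurstfishError, RuntimeError):
    """An iterative fit failed to converge.

    Carries the best parameters seen so far in ``params`` (may be None).
    """

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params
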