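"""Exception hierarchy shared across the package."""


class MixedStockError(Exception):
    """Base class for all package errors."""


class ValidationError(MixedStockError):
    """Input data violated a structural contract (bad counts, label mismatch...)."""


class ConvergenceError(MixedStockError):
    """MCMC diagnostics exceeded the configured PSRF threshold."""
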