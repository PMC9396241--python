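"""Exception types shared across the package."""


class ContractError(ValueError):
    """An operation was called with inputs violating its documented contract."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent."""


class MissingDataError(ValueError):
    """Required data (a map, a feature, a join key) is absent; never imputed silently."""


class ConvergenceError(RuntimeError):
    """An iterative fit exhausted all restarts without a usable solution."""
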