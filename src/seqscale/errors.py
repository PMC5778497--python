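"""Exception types shared across the package."""


class MaskGrammarError(ValueError):
    """Raised when a k-mer mask string violates the N/X/C grammar."""


class FileFormatError(IOError):
    """Raised when a container file is truncated or its header is inconsistent."""


class ConfigError(ValueError):
    """Raised when components built with incompatible parameters are combined."""
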