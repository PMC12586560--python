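"""Exception types shared across the package."""


class FFCNNError(Exception):
    """Base class for package errors."""


class FormatError(FFCNNError, ValueError):
    """A file does not follow the container format it claims to be."""


class ConsistencyError(FFCNNError, ValueError):
    """Two inputs that must agree (shapes, counts, class numbers) do not."""


class CapabilityError(FFCNNError, ValueError):
    """The request is outside what the component can provide."""


class ConfigurationError(FFCNNError, ValueError):
    """A configuration value or combination is invalid."""
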