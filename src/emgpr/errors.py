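"""Exception hierarchy for the emgpr pipeline.

Every error raised by the library derives from :class:`EMGError`, so callers
(notably the CLI) can catch one base class and exit with a message.
"""


class EMGError(Exception):
    """Base class for all emgpr errors."""


class FormatError(EMGError):
    """A recording or sidecar file is malformed (ragged columns, bad header...)."""


class ConfigError(EMGError):
    """A configuration is inconsistent with the data it is applied to."""


class ParameterError(EMGError, ValueError):
    """A function argument is out of its valid range."""


class TrainingError(EMGError):
    """The training set cannot support fitting (too few classes/samples)."""


class DataError(EMGError):
    """Input data contains non-finite or otherwise unusable values."""


class ProtocolError(EMGError):
    """A recording does not cover the session protocol it is paired with."""
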