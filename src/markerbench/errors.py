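"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError/FormatError -> 1,
PluginError -> 2.
"""


class MarkerBenchError(Exception):
    """Base class for all markerbench errors."""


class FormatError(MarkerBenchError):
    """A file does not parse as the expected dialect (names file/line)."""


class ValidationError(MarkerBenchError):
    """Parsed data violates a structural invariant."""


class PluginError(MarkerBenchError):
    """An external selection plugin failed; carries captured stderr."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message)
        self.stderr = stderr
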