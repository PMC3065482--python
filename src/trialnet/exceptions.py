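"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Invalid generator / model / study configuration."""


class StageError(RuntimeError):
    """A study pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
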