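"""Exception hierarchy for jawkin."""


class JawkinError(Exception):
    """Base class for all jawkin errors."""


class FormatError(JawkinError):
    """A marker CSV file does not conform to the <label>_X/_Y/_Z dialect."""


class ConfigError(JawkinError):
    """A study configuration is inconsistent or refers to unknown entities."""


class AlignmentError(JawkinError):
    """Frame-aligned inputs (pose or gape series) have mismatched lengths."""


class PipelineError(JawkinError):
    """The batch pipeline could not produce any usable output."""
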