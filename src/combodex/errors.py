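"""Exception hierarchy shared across the pipeline."""


class CombodexError(Exception):
    """Base class for all combodex errors."""


class FormatError(CombodexError):
    """Malformed input table (missing column, bad enum, unparseable row)."""


class NormalizationError(CombodexError):
    """Raw signals cannot be normalized (e.g. no control wells)."""


class GroupingError(CombodexError):
    """Wells cannot be grouped into a consistent dose-response series."""


class InsufficientDataError(CombodexError):
    """Too few usable observations for the requested fit."""


class ConfigError(CombodexError):
    """Invalid run configuration."""
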