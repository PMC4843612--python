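"""Exception hierarchy shared across the package."""


class DyadannotError(Exception):
    """Base class for all package-specific errors."""


class VocabularyError(DyadannotError):
    """A label or tier does not match the required controlled vocabulary."""


class MissingTierError(DyadannotError):
    """A required tier is absent from a session."""


class GridError(DyadannotError):
    """Two sampled timelines do not share the same sampling grid."""


class RangeError(DyadannotError):
    """A requested window falls outside the annotated session."""


class PairingError(DyadannotError):
    """Two objects that must refer to the same pair/stage do not."""


class InsufficientDataError(DyadannotError):
    """Not enough sessions/annotations to compute the requested statistic."""


class EafParseError(DyadannotError):
    """Malformed EAF (XML) input."""


class EafReferenceError(DyadannotError):
    """An EAF annotation references a time slot that does not exist."""


class CsvFormatError(DyadannotError):
    """The CSV interval table does not follow the 5-column dialect."""


class CsvRowError(DyadannotError):
    """A single CSV row is invalid; the message names the row number."""


class SessionValidationError(DyadannotError):
    """A session failed structural validation; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"session failed validation: {lines}")


class ConfigError(DyadannotError):
    """A generator or tier configuration is inconsistent."""
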