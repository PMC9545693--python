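"""Exception hierarchy for the DDI concordance pipeline."""


class DDIError(Exception):
    """Base class for all package errors."""


class ConfigError(DDIError):
    """Invalid or incomplete run configuration."""


class SelfPairError(DDIError, ValueError):
    """Both members of an interacting pair resolve to the same ingredient."""


class UnknownSeverityLabel(DDIError, KeyError):
    """A severity label is absent from the resource's closed vocabulary."""


class UnknownEvidenceLabel(DDIError, KeyError):
    """An evidence label is absent from the resource's closed vocabulary."""


class EmptyReferenceSet(DDIError, ZeroDivisionError):
    """Coverage rate requested against an empty reference set."""


class MissingEvidence(DDIError):
    """A resource expected to rate every record has an unrated shared record."""


class DegenerateTrainingSet(DDIError, ValueError):
    """A binary training set contains only one class."""


class IdMismatch(DDIError, KeyError):
    """Automatic and manual annotation sets cover different sentence ids."""


class InfeasibleConfig(DDIError, ValueError):
    """A simulation configuration cannot be realised."""


class MissingTemplate(DDIError, KeyError):
    """No sentence template available for a requested advice category."""
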