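"""Exception hierarchy for the OHRA toolkit."""


class OhraError(Exception):
    """Base class for all toolkit errors."""


class RegistryError(OhraError):
    """A hazard registry file could not be parsed or validated."""


class DuplicateChemicalError(RegistryError):
    """Two registry rows share the same chemical name."""


class MissingParameterError(OhraError):
    """A toxicological parameter required by a method is absent.

    Raised e.g. when the EPA engine is asked to score a hazard without an
    RfC, or a concentration ratio is requested against an absent OEL.
    """


class ParameterError(OhraError, ValueError):
    """An input value is outside the domain an operation accepts."""


class ScaleError(OhraError):
    """A risk level does not belong to the method's ordinal scale."""


class UnknownPhraseError(OhraError):
    """A risk phrase has no hazard-band mapping in the method config."""
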