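"""Exception hierarchy for plastotype."""


class PlastotypeError(Exception):
    """Base class for all plastotype errors."""


class ParameterError(PlastotypeError, ValueError):
    """A parameter is outside its documented domain."""


class ContractError(PlastotypeError, ValueError):
    """A documented precondition was violated by the caller."""


class CoordinateError(PlastotypeError, ValueError):
    """A coordinate falls outside the sequence it refers to."""


class FormatError(PlastotypeError, ValueError):
    """An input file does not conform to its declared format."""


class CapacityError(PlastotypeError, ValueError):
    """A construction does not fit in the space allotted to it."""


class CapabilityError(PlastotypeError, ValueError):
    """The request exceeds a documented built-in limit."""
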