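"""Exception types shared across the package."""


class EmbryoDoseError(Exception):
    """Base class for package errors."""


class ValidationError(EmbryoDoseError, ValueError):
    """A parameter or input fails its contract."""


class GeometryError(EmbryoDoseError, ValueError):
    """A geometric specification is internally inconsistent
    (e.g. a nucleus placed outside the embryo envelope)."""


class PhantomFormatError(EmbryoDoseError, ValueError):
    """The phantom text file violates the format contract."""


class ChannelMixupError(EmbryoDoseError, ValueError):
    """Compartment masks are inconsistent in a way that suggests the
    colour channels were swapped (e.g. chromatin mostly outside nucleus)."""


class UndefinedDoseError(EmbryoDoseError, ZeroDivisionError):
    """Specific energy requested for a massless (empty) compartment."""
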