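"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`PetquantError`, so callers can distinguish pipeline failures from
programming errors.
"""


class PetquantError(Exception):
    """Base class for all petquant errors."""


class ParameterError(PetquantError, ValueError):
    """A numeric argument violates its contract (e.g. non-positive half-life)."""


class SpecError(PetquantError, ValueError):
    """A phantom specification is internally inconsistent."""


class FormatError(PetquantError, ValueError):
    """An on-disk artifact is malformed or inconsistent with its sidecar."""


class ConfigError(PetquantError, ValueError):
    """A pipeline configuration failed validation.

    Carries the full list of violations in :attr:`errors`.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))
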