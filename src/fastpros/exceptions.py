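"""Exception hierarchy for fastpros."""


class FastProsError(Exception):
    """Base class for all fastpros errors."""


class ModelFormatError(FastProsError):
    """A model file could not be parsed, or lacks required structure."""


class ConfigurationError(FastProsError):
    """A configuration value refers to something absent from the model."""


class LookupError_(FastProsError):
    """A metabolite, reaction or gene id does not resolve."""


class InfeasibleModelError(FastProsError):
    """An LP that must be feasible (e.g. the wild-type model) is not."""


class SolverError(FastProsError):
    """The LP/MILP solver returned an unexpected status."""

    def __init__(self, message: str, status: str | None = None):
        super().__init__(message)
        self.status = status
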