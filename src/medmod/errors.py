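"""Exception hierarchy shared across the package."""


class MedModError(Exception):
    """Base class for all package-specific errors."""


class LoadError(MedModError):
    """A file or document could not be parsed into a domain object.

    Carries ``pointer``, a JSON-pointer-style path naming the offending
    location inside the document (``""`` for whole-document problems).
    """

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(f"{pointer or '/'}: {message}" if pointer else message)
        self.pointer = pointer


class StructureError(MedModError):
    """A trace is structurally broken (e.g. dangling causal references);
    distinct from conformance violations, which are returned as records."""


class ResolutionError(MedModError):
    """A name (activity, attribute, enumeration, interval) does not resolve."""


class TypeMismatchError(MedModError):
    """An operator or constant is illegal for the attribute's data type."""


class QueryArgumentError(MedModError):
    """An out-of-range query argument (e.g. partition k, inverted window)."""


class ConfigurationError(MedModError):
    """An invalid simulation configuration (e.g. branch weights not summing
    to one, realized counts outside declared cardinality bounds)."""


class SimulationError(MedModError):
    """Simulation could not complete (e.g. runaway control-flow loop)."""
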