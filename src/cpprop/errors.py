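"""Exception hierarchy for cpprop."""


class CppropError(Exception):
    """Base class for all cpprop errors."""


class GeneratorError(CppropError):
    """Synthetic problem generation could not produce a stable problem."""


class SingularityError(CppropError):
    """Undamped response equation evaluated exactly at a pole."""


class ContainerError(CppropError):
    """Problem-container I/O failure (base)."""


class MalformedHeaderError(ContainerError):
    """Container header is missing or inconsistent."""


class UnsupportedVersionError(ContainerError):
    """Container format version is not supported by this reader."""


class DimensionMismatchError(ContainerError):
    """Array shapes disagree with the header dimensions."""


class MissingComponentError(CppropError):
    """A requested operator component has no solved response equation."""


class UnmappedIndexError(CppropError):
    """An orbital parameter index has no (p, q) entry in the pair map."""
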