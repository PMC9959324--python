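"""Exception hierarchy shared across the package."""


class HsiPathoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HsiPathoError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(HsiPathoError):
    """Metadata and data disagree (e.g. wavelength count vs band count)."""


class DegenerateReferenceError(HsiPathoError):
    """White and dark calibration references coincide at a used pixel."""


class EmptySelectionError(HsiPathoError):
    """A band window or band-sampling request selects nothing."""


class SizeError(HsiPathoError):
    """A patch or kernel size is incompatible with the data dimensions."""


class RankError(HsiPathoError):
    """Too few observations for the requested number of PCA components."""


class ShapeError(HsiPathoError):
    """Array shapes are incompatible with the requested operation."""


class TopologyError(HsiPathoError):
    """A network topology produces a non-positive layer dimension."""


class ParameterError(HsiPathoError):
    """A hyperparameter is outside its admissible range."""


class LeakageError(HsiPathoError):
    """Case-level information would flow between train/val/test splits."""


class ConfigError(HsiPathoError):
    """An experiment or phantom configuration is infeasible."""


class SplitError(HsiPathoError):
    """Too few cases to form the requested splits."""


class InputError(HsiPathoError):
    """Malformed user input (mismatched lengths, empty collections...)."""
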