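"""Exception hierarchy for the MR screening pipeline."""


class MrScreenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MrScreenError):
    """A mandatory column could not be resolved in an input file."""


class EmptyDatasetError(MrScreenError):
    """No valid rows survived parsing/validation."""


class ConfigError(MrScreenError):
    """Invalid configuration value."""


class InsufficientSnpsError(MrScreenError):
    """Too few SNPs for the requested estimator or diagnostic."""


class DegenerateInputError(MrScreenError):
    """Input is degenerate (e.g. all exposure effects are zero)."""


class EmptyHarmonizationError(MrScreenError):
    """Harmonization retained no SNPs; the analysis cannot proceed."""


class InsufficientDataError(MrScreenError):
    """Too few data points for LD score regression."""


class InsufficientOverlapError(MrScreenError):
    """Too few shared SNPs between two LDSC inputs."""


class DegenerateCorrectionError(MrScreenError):
    """Outlier correction removed every SNP."""
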