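"""Exception hierarchy shared across the package."""


class QtlConvergeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(QtlConvergeError):
    """Invalid or inconsistent pipeline configuration."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class SimulationError(QtlConvergeError):
    """Invalid parameters passed to a synthetic-data generator."""


class FormatError(QtlConvergeError):
    """A file does not conform to its declared format."""


class CorpusError(QtlConvergeError):
    """Invalid gene-set corpus (empty sets, duplicate ids, ...)."""


class ScanError(QtlConvergeError):
    """Genome scan or model fit could not be carried out."""
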