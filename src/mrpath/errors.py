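"""Exception hierarchy shared across the pipeline stages."""


class MrpathError(Exception):
    """Base class for all package errors."""


class ConfigError(MrpathError):
    """Invalid simulation or pipeline configuration."""


class FormatError(MrpathError):
    """Malformed input file (missing column, bad matrix, out-of-range value)."""


class AnalysisError(MrpathError):
    """A statistical operation received inputs it cannot handle."""


class CollinearityError(AnalysisError):
    """Rank-deficient regression design; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {', '.join(self.columns)}")
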