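"""Exception hierarchy shared across the package."""


class MatchromError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MatchromError):
    """A file does not conform to the expected tabular/FASTA/Newick format."""


class ValidationError(MatchromError):
    """Structurally well-formed input violates a dataset invariant."""


class AlignmentError(MatchromError):
    """Sequences that must be aligned (equal length, in frame) are not."""


class NewickParseError(FormatError):
    """Malformed Newick input."""


class CorrectionUndefinedError(MatchromError):
    """Jukes-Cantor correction undefined: proportion of differences >= 0.75.

    Carries the offending raw proportion in ``proportion``.
    """

    def __init__(self, proportion: float, context: str = ""):
        self.proportion = proportion
        msg = f"JC correction undefined for p={proportion:.6g} (requires p < 0.75)"
        if context:
            msg += f" [{context}]"
        super().__init__(msg)


class ConfigError(MatchromError):
    """Invalid or infeasible pipeline/simulation configuration."""
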