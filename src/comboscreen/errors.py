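"""Exception hierarchy shared across the pipeline stages."""


class ComboScreenError(Exception):
    """Base class for all package errors."""


class NormalizationError(ComboScreenError):
    """Raised when a plate group cannot be normalized (no/zero controls, bad wells)."""


class FitError(ComboScreenError):
    """Raised when a median-effect fit is impossible or degenerate."""


class ParameterError(ComboScreenError, ValueError):
    """Invalid user-supplied parameter (ladder settings, doses, p-values...)."""


class EmptyProfileError(ComboScreenError):
    """A combination-index profile has no usable (interior fraction-affected) points."""


class CompletenessError(ComboScreenError):
    """A screen matrix is missing (treatment, model) cells and cannot be ranked."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "screen matrix incomplete; missing (treatment, model) cells: "
            + ", ".join(f"({t!r}, {m!r})" for t, m in self.missing)
        )


class CSVFormatError(ComboScreenError):
    """Strict CSV validation failure; carries per-row messages with line numbers."""

    def __init__(self, path, problems):
        self.path = str(path)
        self.problems = list(problems)
        detail = "; ".join(self.problems[:20])
        if len(self.problems) > 20:
            detail += f"; ... ({len(self.problems) - 20} more)"
        super().__init__(f"{self.path}: {detail}")


class ConfigError(ComboScreenError):
    """Invalid screen configuration (unknown drug, bad level, ...)."""


class SimulationError(ComboScreenError):
    """Ground-truth generator failure (e.g. Loewe bisection non-convergence)."""


class StageError(ComboScreenError):
    """Pipeline stage failure wrapping the underlying error with the stage name."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
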