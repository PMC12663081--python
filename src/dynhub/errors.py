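"""Exception types shared across the pipeline stages."""


class DynhubError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DynhubError, ValueError):
    """A parameter violates its documented contract."""


class FormatError(DynhubError, ValueError):
    """An input file does not conform to the expected delimited-text layout."""


class StructureError(DynhubError, ValueError):
    """Two pipeline objects that must agree (e.g. window counts) do not."""


class DegenerateWindowError(DynhubError):
    """A sliding window contains a zero-variance node, so Pearson r is undefined."""

    def __init__(self, subject_id: str, window: int, node: int):
        self.subject_id = subject_id
        self.window = window
        self.node = node
        super().__init__(
            f"zero within-window variance: subject={subject_id!r}, "
            f"window={window}, node={node}"
        )


class DegenerateStatisticError(DynhubError):
    """A correlation is undefined because one input has zero rank variance."""
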