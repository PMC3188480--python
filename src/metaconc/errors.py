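"""Exception types shared across the package."""


class MetaconcError(Exception):
    """Base class for all package errors."""


class StructureParseError(MetaconcError):
    """A molecular structure could not be parsed.

    Carries the record identifier so batch runs can point at the
    offending input line.
    """

    def __init__(self, record_id: str, detail: str = ""):
        self.record_id = record_id
        self.detail = detail
        msg = f"could not parse structure for record {record_id!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class EmbeddingError(MetaconcError):
    """3D conformer generation failed for a molecule."""

    def __init__(self, record_id: str, seed: int):
        self.record_id = record_id
        self.seed = seed
        super().__init__(
            f"3D embedding failed for record {record_id!r} (seed {seed}); "
            "retry with a different seed"
        )


class MissingRadiusError(MetaconcError):
    """The van-der-Waals radius table has no entry for an element."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"no van-der-Waals radius for element {element!r}")


class DegenerateInputError(MetaconcError):
    """Statistical input is degenerate (too few points or zero variance)."""


class TableJoinError(MetaconcError):
    """Descriptor and concentration tables share no metabolite ids."""

    def __init__(self, unmatched: list):
        self.unmatched = list(unmatched)
        super().__init__(
            "descriptor and concentration tables share no ids; "
            f"unmatched: {', '.join(map(str, self.unmatched[:10]))}"
        )


class TableFormatError(MetaconcError):
    """A tabular input file is malformed (bad cell, duplicate id, ...)."""


class PipelineStageError(MetaconcError):
    """A pipeline stage failed; names the stage for the log."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
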