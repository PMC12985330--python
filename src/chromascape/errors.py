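"""Exception hierarchy used across the pipeline."""


class ChromascapeError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(ChromascapeError):
    """A scalar/vector parameter violates its contract."""


class EmptyInputError(ChromascapeError):
    """A collection that must be non-empty was empty."""


class InvalidGeometryError(ChromascapeError):
    """Patch geometry violates its contract (overlap, zero area, ...)."""


class InvalidInputError(ChromascapeError):
    """Tabular/matrix input violates its schema or invariants."""


class MissingSpeciesError(ChromascapeError):
    """A species id referenced by a community is absent from a table or tree."""


class UndefinedStatisticError(ChromascapeError):
    """The requested statistic is undefined for the given input."""


class DegenerateTreeError(ChromascapeError):
    """A phylogeny violates the preconditions of a tree statistic."""


class CollinearityError(ChromascapeError):
    """The model design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class DegenerateGroupingError(ChromascapeError):
    """The random-effect grouping has too few levels to estimate a variance."""
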