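"""Shared exception types."""


class InsufficientDataError(ValueError):
    """A statistic was requested from an empty (or too small) sample."""


class CapacityError(ValueError):
    """A resource pool is too small for the requested allocation."""


class NoObjectError(ValueError):
    """No changed region was found between two images."""


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g. a constant image)."""


class SchemaError(ValueError):
    """A response table violates the canonical schema.

    Attributes
    ----------
    problems : list of (row_index, message)
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = [f"row {i}: {msg}" for i, msg in self.problems[:20]]
        more = len(self.problems) - len(lines)
        if more > 0:
            lines.append(f"... and {more} more")
        super().__init__("invalid response table:\n" + "\n".join(lines))
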