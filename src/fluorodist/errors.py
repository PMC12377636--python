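"""Exception hierarchy shared across the pipeline."""


class FluorodistError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FluorodistError):
    """A configuration value violates its invariant; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class RangeError(FluorodistError, ValueError):
    """An intensity or descriptor value lies outside its permitted range."""


class DegenerateBackgroundError(FluorodistError, ValueError):
    """System background >= 127.5: the exposure-adjustment slope is undefined
    or negative and the image is unusable."""


class EmptyInputError(FluorodistError, ValueError):
    """An operation requiring at least one record received none."""


class LabelError(FluorodistError, ValueError):
    """A scoring-quantile label outside {-1, 0, 1, 2, 3}."""


class SchemaError(FluorodistError, ValueError):
    """A tabular input is missing required columns."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing required column(s): {', '.join(self.missing)}")


class StructureParseError(FluorodistError, ValueError):
    """A SMILES/structure string could not be parsed."""


class CountConsistencyError(FluorodistError, ValueError):
    """Hypergeometric counts are infeasible (m > x, m > n, n > y, x > y, ...)."""


class StratumSpecError(FluorodistError, ValueError):
    """A stratum specification references an unknown organ, skeleton, region
    or charge filter."""


class JoinError(FluorodistError, ValueError):
    """Descriptor and intensity tables cannot be joined on compound id."""

    def __init__(self, orphan_ids: list[str]):
        self.orphan_ids = list(orphan_ids)
        shown = ", ".join(map(str, self.orphan_ids[:10]))
        more = "" if len(self.orphan_ids) <= 10 else f" (+{len(self.orphan_ids) - 10} more)"
        super().__init__(f"intensity rows with no matching descriptor id: {shown}{more}")
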