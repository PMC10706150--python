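"""Exception hierarchy shared across the pipeline stages."""


class WoodsmokeError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(WoodsmokeError, ValueError):
    """An input value violates a precondition (e.g. negative cf1 mass)."""


class InvalidCountsError(WoodsmokeError, ValueError):
    """Cumulative size-channel counts are not monotone non-increasing."""


class MissingHourError(WoodsmokeError, ValueError):
    """Both laser channels are missing for an hour that was asked to be fused."""


class DegenerateSeriesError(WoodsmokeError, ValueError):
    """A statistic is undefined because a series has zero variance or too few points."""


class SchemaError(WoodsmokeError, ValueError):
    """An input file is missing mandatory columns or is otherwise unreadable."""


class TimestampError(WoodsmokeError, ValueError):
    """Timestamps are unsorted, duplicated, or carry a daylight-saving offset."""
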