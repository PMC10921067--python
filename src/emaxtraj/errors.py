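"""Exception types shared across the pipeline stages."""


class SpecValidationError(ValueError):
    """A configuration or cohort specification field is invalid."""


class InsufficientDataError(ValueError):
    """Too few observations to perform the requested computation."""


class EmptySeriesError(ValueError):
    """No age band contains any observation; the cohort is unusable."""


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""
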