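"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A file or table violates its expected layout (duplicates, ragged rows, bad coordinates)."""


class ConfigError(ValueError):
    """An invalid configuration: bad simulation dimensions, incomplete energy tables."""


class ConsistencyError(ValueError):
    """Inputs that must refer to the same universe of identifiers disagree."""
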