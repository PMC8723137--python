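"""Exception hierarchy for voxscreen."""


class VoxscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VoxscreenError):
    """A configuration (chain map, channel map, grid spec, ...) is inconsistent."""


class InputError(VoxscreenError):
    """An input structure, table or argument violates a precondition."""
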