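class PushPullError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PushPullError, ValueError):
    """Invalid user input: malformed data, out-of-range values, bad config."""
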