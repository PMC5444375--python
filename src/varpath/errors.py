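"""Labeled error types raised by varpath.

Every anticipated failure mode raises a subclass of :class:`VarpathError`
with a message naming the offending input, so callers (and the CLI) can
surface the stage that failed without a traceback hunt.
"""


class VarpathError(Exception):
    """Base class for all varpath errors."""


class ValidationError(VarpathError):
    """Invalid input data or configuration (bad shapes, labels, ranges)."""


class EnumerationCapError(VarpathError):
    """Exact-test enumeration would exceed the composition cap.

    Callers should fall back to the chi-squared test or the Monte-Carlo
    multinomial test.
    """


class FitError(VarpathError):
    """Model fitting (mixture EM) failed for every candidate."""
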