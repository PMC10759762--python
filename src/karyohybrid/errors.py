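"""Exception hierarchy shared across the package.

Every error carries a short machine-readable ``error_class`` so the CLI can
map failures to stable exit diagnostics.
"""


class KaryoHybridError(Exception):
    """Base class for all package errors."""

    error_class = "generic"


class InputError(KaryoHybridError):
    """Missing, malformed or inconsistent input data."""

    error_class = "input"


class InvalidMeasurementError(InputError):
    """A chromosome measurement that cannot be interpreted (e.g. both arms zero)."""

    error_class = "measurement"


class PairingError(KaryoHybridError):
    """Homolog pairing failed (odd chromosome count within a type class)."""

    error_class = "pairing"


class UnbalancedParentError(KaryoHybridError):
    """A parental karyotype with an odd per-type count cannot form balanced gametes."""

    error_class = "unbalanced-parent"


class FormulaError(InputError):
    """A karyotype formula string that does not parse or is internally inconsistent."""

    error_class = "formula"


class NoInvertedRepeatError(KaryoHybridError):
    """No inverted repeat at or above the minimum length: non-quadripartite input."""

    error_class = "no-ir"


class InsufficientHomologyError(KaryoHybridError):
    """Too few shared unique anchors to align two sequences collinearly."""

    error_class = "insufficient-homology"


class ReferenceMismatchError(KaryoHybridError):
    """Variant sets being compared were called against different references."""

    error_class = "reference-mismatch"
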