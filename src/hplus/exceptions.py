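"""Exception hierarchy.

``InputError`` maps to CLI exit code 2 (malformed input), while
``DegeneratePartitionError`` maps to exit code 1 (structurally valid input on
which the requested statistic is undefined, e.g. a single-cluster labelling).
"""


class HplusError(Exception):
    """Base class for all package errors."""


class InputError(HplusError, ValueError):
    """Malformed or inconsistent user input (shapes, files, parameters)."""


class DegeneratePartitionError(HplusError, ValueError):
    """Partition admits no within- or no between-cluster distances.

    H+ divides by |D_W|*|D_B|; a partition with a single cluster (no between
    distances) or all-singleton clusters (no within distances) leaves it
    undefined.  Instances may carry a ``partial`` dict with the quantities
    that *are* defined (s, g_plus, alpha).
    """

    def __init__(self, message: str, partial: dict | None = None):
        super().__init__(message)
        self.partial = partial or {}
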