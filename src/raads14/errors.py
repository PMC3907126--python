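"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`UsageError` -> 2,
:class:`FormatError` -> 3.
"""


class Raads14Error(Exception):
    """Base class for all package errors."""


class UsageError(Raads14Error, ValueError):
    """The caller asked for something the inputs cannot support
    (empty group, quota larger than a domain, out-of-range statistic...)."""


class FormatError(Raads14Error, ValueError):
    """Malformed external input: unknown category label, bad CSV header,
    broken instrument definition."""


class DegenerateDataError(Raads14Error, ValueError):
    """The computation is undefined on these data (zero total-score
    variance, singular correlation matrix)."""
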