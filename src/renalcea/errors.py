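"""Exception hierarchy.

Configuration problems and numerical infeasibilities are kept distinct so
callers (and the CLI exit codes) can tell a bad input file from a bad number.
"""


class RenalCeaError(Exception):
    """Base class for all package errors."""


class ConfigError(RenalCeaError):
    """A configuration file is missing, malformed, or incomplete."""


class ValidationError(ConfigError):
    """One or more parameter entries violate their invariants.

    ``problems`` lists every offending entry, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class InfeasibleMomentsError(RenalCeaError):
    """Mean/SE pair admits no distribution of the requested family."""


class DomainError(RenalCeaError):
    """An argument is outside the mathematical domain of an operation."""
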