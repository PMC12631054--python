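"""Exception hierarchy shared across the package."""


class BiasNetError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BiasNetError, ValueError):
    """A probability or slider value lies outside its permitted domain."""


class ValidationError(BiasNetError, ValueError):
    """A record, table, or configuration fails schema validation."""


class EvidenceImpossibleError(BiasNetError, ZeroDivisionError):
    """The observed testimony has probability zero under the given priors."""


class UndefinedLLRError(BiasNetError, ZeroDivisionError):
    """Both conditional likelihoods are zero; the likelihood ratio is 0/0."""


class UndefinedMetricError(BiasNetError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero-variance predictor)."""
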