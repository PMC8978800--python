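"""Exception hierarchy.

Every anticipated failure raises a named subclass of :class:`DwppiError`
so callers (and the CLI) can distinguish data problems from usage bugs.
"""


class DwppiError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(DwppiError):
    """Malformed FASTA: bad header, empty sequence, or duplicate record ID."""


class EdgeListFormatError(DwppiError):
    """Edge-list line does not contain exactly two identifiers."""


class PredictionWriteError(DwppiError):
    """Pairs and scores disagree in length, or scores fall outside [0, 1]."""


class ConfigError(DwppiError):
    """Run configuration violates an invariant (k < 1, folds < 2, ...)."""


class GraphError(DwppiError):
    """Graph construction received no edges or an otherwise invalid input."""


class SamplingError(DwppiError):
    """Negative-pair sampling asked for more non-edges than exist."""


class VocabularyError(DwppiError):
    """Empty vocabulary, or a token/vertex missing from a trained vocabulary."""


class WalkError(DwppiError):
    """Random-walk parameters invalid (walk_length < 1, ...)."""


class ModelError(DwppiError):
    """Classifier input shapes inconsistent, non-finite values, or a
    single-class training set."""


class EvaluationError(DwppiError):
    """Metric computation impossible: empty input, single class for AUC,
    or fewer pairs than folds."""
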