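"""Exception hierarchy shared across the toolkit."""


class GeneDesignError(Exception):
    """Base class for all toolkit errors."""


class SequenceError(GeneDesignError):
    """Invalid sequence content (bad letters, partial codons, empty input)."""


class TableError(GeneDesignError):
    """Malformed or inconsistent codon-usage table."""


class SearchError(GeneDesignError):
    """Unknown enzyme name, unknown predefined set, or bad query input."""


class OptimizationError(GeneDesignError):
    """Unsatisfiable optimization request or missing resources."""


class StrategyError(GeneDesignError):
    """Invalid optimization-strategy or construct configuration."""
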