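"""Exception hierarchy for probecap."""


class ProbecapError(Exception):
    """Base class for all probecap errors."""


class FastaError(ProbecapError):
    """Malformed FASTA input (duplicate ids, bad characters, empty bodies)."""


class ConfigError(ProbecapError):
    """Invalid or inconsistent run configuration."""


class PipelineError(ProbecapError):
    """A pipeline stage failed; the message names the stage."""
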