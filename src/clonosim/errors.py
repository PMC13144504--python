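"""Package-wide exception types."""


class ClonosimError(Exception):
    """Base class for all clonosim errors."""


class CapacityError(ClonosimError):
    """The lattice cannot hold the requested number of cells."""


class NoGrowthError(ClonosimError):
    """Growth to the target size is impossible (zero birth and death rates)."""


class PartitionError(ClonosimError):
    """A dissection plan failed to partition the occupied sites."""


class FastqParseError(ClonosimError):
    """A FASTQ record could not be parsed.

    Carries the 1-based record number at which parsing failed.
    """

    def __init__(self, record_number: int, message: str):
        self.record_number = record_number
        super().__init__(f"FASTQ record {record_number}: {message}")


class ConfigError(ClonosimError):
    """Invalid configuration (e.g. duplicate sample indexes)."""
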