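"""Exception hierarchy for the sldnet pipeline."""


class SldnetError(Exception):
    """Base class for all sldnet errors."""


class InvalidItemError(SldnetError):
    """An item record violates its own constraints (score range, max score)."""


class MappingError(SldnetError):
    """Item records map to an unexpected or inconsistent symptom scale."""


class DuplicateRecordError(SldnetError):
    """Two records exist for the same (patient, week, instrument, item)."""


class DegenerateSeriesError(SldnetError):
    """A symptom series has too few observations or zero variance to standardize."""


class IneligiblePatientError(SldnetError):
    """Patient has fewer observed weeks than the eligibility minimum."""


class ReliabilityUndefinedError(SldnetError):
    """Too little overlap/variance to compute a reliability index."""


class ZeroVarianceError(SldnetError):
    """An outcome or predictor has zero variance where variance is required."""


class ConfigInfeasibleError(SldnetError):
    """A generative configuration cannot produce a stable lag matrix."""


class PipelineStageError(SldnetError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
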