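"""Exception hierarchy for the quality-impact model."""


class QualimpactError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QualimpactError, ValueError):
    """An input violated a documented invariant (non-monotone scores, bad weights...)."""


class DataUnavailableError(QualimpactError):
    """A measure x segment combination has no benchmark data.

    This mirrors real gaps in the public performance tables (e.g. no Medicaid
    distribution exists for the colorectal-cancer-screening measure) and must be
    surfaced explicitly rather than treated as a zero score.
    """

    def __init__(self, measure_id: str, segment: str, detail: str = ""):
        self.measure_id = measure_id
        self.segment = segment
        msg = f"data unavailable for measure {measure_id!r}, segment {segment!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
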