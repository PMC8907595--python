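"""Exception hierarchy shared across the package."""


class FaceswellError(Exception):
    """Base class for all errors raised by faceswell."""


class InvalidAnnotationError(FaceswellError):
    """A landmark annotation violates its geometric contract
    (too few outline vertices, self-intersecting outline, coincident
    canthi, nose tip outside the face outline, non-finite coordinates)."""


class InvalidMeasurementError(FaceswellError):
    """A measurement violates a contract required by calibration,
    e.g. H2 < H1, which no valid landmark set can produce."""


class DegeneratePoseError(InvalidMeasurementError):
    """The nose tip lies on the canthus line (H1 = 0); the head pitch
    proxy is undefined and the photograph cannot be calibrated."""


class CalibrationDomainError(FaceswellError):
    """Non-positive area/length fed to a calibration stage."""


class GenerationError(FaceswellError):
    """The synthetic projection placed a landmark behind the camera or
    outside the image frame."""


class SchemaError(FaceswellError):
    """An input file does not match the expected column schema."""


class RowParseError(FaceswellError):
    """A single CSV row could not be parsed; carries the 1-based line
    number in ``line``."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line
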