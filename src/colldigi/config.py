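"""Project-wide defaults shared across the pipeline modules."""

from __future__ import annotations

# Barcode payload: human-readable prefix + zero-padded counter. The prefix and
# width are configurable per project; these defaults follow the NHM-style
# accession-number shape.
BARCODE_PREFIX = "NHMUK"
BARCODE_DIGITS = 9

# Label crop geometry: the rightmost quarter of the frame holds the label
# panel; crops are stored at this fixed size regardless of source resolution.
LABEL_CROP_FRACTION = 0.25
LABEL_SIZE = (800, 1219)  # (width, height) pixels

JPEG_QUALITY = 92

# Workflow stages in monotone order.
STATUSES = ("imaged", "transcribed", "normalized", "georeferenced", "exported")

ROLES = frozenset({"transcriber", "georeferencer", "scrutineer", "data_manager"})

# Sites with at least this many specimens are georeferenced first.
TRIAGE_THRESHOLD = 5

# Advisory per-site time budget (minutes) for the split-pass georeferencing
# stage; metadata only, never enforced.
SPLIT_PASS_MINUTES = 15

EARTH_RADIUS_M = 6_371_000.0


def format_barcode(number: int, prefix: str = BARCODE_PREFIX, digits: int = BARCODE_DIGITS) -> str:
    return f"{prefix}{number:0{digits}d}"
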