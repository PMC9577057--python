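"""Pixel/physical unit conversions at scanner resolution."""

DEFAULT_MICRONS_PER_PX = 0.49


def px_to_microns(px: float, microns_per_px: float = DEFAULT_MICRONS_PER_PX) -> float:
    """Level-0 pixels to microns."""
    return px * microns_per_px


def mm_to_px(mm: float, microns_per_px: float = DEFAULT_MICRONS_PER_PX) -> float:
    """Millimetres to level-0 pixels."""
    return mm * 1000.0 / microns_per_px
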