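"""Canonical terminal class labels and their integer encoding.

Index 0 is always ``no_fracture``; the four fracture types follow in fixed
order. Every module communicates labels either as these strings or as the
corresponding indices, so the encoding is defined exactly once.
"""

CLASSES: tuple[str, ...] = (
    "no_fracture",
    "nondisplaced",
    "ad_latus",
    "cum_contractione",
    "cum_distractione",
)

FRACTURE_CLASSES: tuple[str, ...] = CLASSES[1:]

DISPLACED_CLASSES: tuple[str, ...] = ("ad_latus", "cum_contractione", "cum_distractione")

_INDEX = {name: i for i, name in enumerate(CLASSES)}


def label_index(name: str) -> int:
    """Integer code of a terminal class name (0 = no_fracture)."""
    try:
        return _INDEX[name]
    except KeyError:
        raise ValueError(f"unknown class label {name!r}; expected one of {CLASSES}") from None


def label_name(index: int) -> str:
    """Terminal class name for an integer code."""
    if not 0 <= index < len(CLASSES):
        raise ValueError(f"class index {index} out of range 0..{len(CLASSES) - 1}")
    return CLASSES[index]
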