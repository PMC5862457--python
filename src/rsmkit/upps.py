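"""Built-in scale definition for the UPPS-P impulsive-behaviour questionnaire.

The 59-item five-dimension structure with the four-item short-form (SUPPS-P)
subsets.  Reverse-keyed items are left empty by default — the published
Spanish-form item keying is not enumerated — and can be supplied by the user.
"""

from __future__ import annotations

from .data import ScaleDefinition

_DIMENSIONS = {
    "negative_urgency": [2, 7, 12, 17, 22, 29, 34, 39, 44, 50, 53, 58],
    "lack_of_premeditation": [1, 6, 11, 16, 21, 28, 33, 38, 43, 48, 55],
    "lack_of_perseverance": [4, 9, 14, 19, 24, 27, 32, 37, 42, 47],
    "sensation_seeking": [3, 8, 13, 18, 23, 26, 31, 36, 41, 46, 51, 56],
    "positive_urgency": [5, 10, 15, 20, 25, 30, 35, 40, 45, 49, 52, 54, 57, 59],
}

_SHORT_FORM = {
    "negative_urgency": [29, 34, 44, 50],
    "lack_of_premeditation": [6, 33, 43, 48],
    "lack_of_perseverance": [4, 27, 37, 42],
    "sensation_seeking": [3, 23, 31, 41],
    "positive_urgency": [40, 45, 49, 52],
}


def _ids(numbers: list[int]) -> list[str]:
    return [f"item{n}" for n in numbers]


def upps_scale_definition(reverse_keyed: frozenset[str] = frozenset()) -> ScaleDefinition:
    """The UPPS-P / SUPPS-P scale layout: 12/11/10/12/14 items, 4-item short forms."""
    return ScaleDefinition(
        dimensions={d: _ids(v) for d, v in _DIMENSIONS.items()},
        short_form={d: _ids(v) for d, v in _SHORT_FORM.items()},
        reverse_keyed=reverse_keyed,
        n_categories=5,
    )
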