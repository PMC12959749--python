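"""The ten-vowel /hVt/ inventory and its corner-vowel subset.

Vowel categories are stored as ASCII ARPABET-style codes so that CSV
files stay encoding-safe; each code maps bijectively to an IPA display
symbol. The mid-central vowel (the "hut" vowel) is carried under code
``AH`` and displayed as /ə/.
"""

from __future__ import annotations

from enum import Enum


class VowelLabel(str, Enum):
    """One of the ten target vowels, keyed by ARPABET-style code."""

    IY = "IY"  # /i/  heat
    IH = "IH"  # /ɪ/  hit
    EH = "EH"  # /ɛ/  het
    EY = "EY"  # /e/  hate
    AE = "AE"  # /æ/  hat
    AH = "AH"  # /ə/  hut
    UW = "UW"  # /u/  hoot
    UH = "UH"  # /ʊ/  hood
    OW = "OW"  # /o/  hote
    AA = "AA"  # /ɑ/  hot

    @property
    def ipa(self) -> str:
        return _IPA[self]

    @property
    def is_corner(self) -> bool:
        return self in CORNER_VOWELS

    @classmethod
    def from_string(cls, value: str) -> "VowelLabel":
        """Resolve a code or IPA symbol, case-insensitively for codes."""
        v = value.strip()
        try:
            return cls(v.upper())
        except ValueError:
            pass
        if v in _FROM_IPA:
            return _FROM_IPA[v]
        raise ValueError(f"unknown vowel label: {value!r}")


_IPA = {
    VowelLabel.IY: "i",
    VowelLabel.IH: "ɪ",
    VowelLabel.EH: "ɛ",
    VowelLabel.EY: "e",
    VowelLabel.AE: "æ",
    VowelLabel.AH: "ə",
    VowelLabel.UW: "u",
    VowelLabel.UH: "ʊ",
    VowelLabel.OW: "o",
    VowelLabel.AA: "ɑ",
}

_FROM_IPA = {ipa: code for code, ipa in _IPA.items()}

#: Articulatorily extreme vowels spanning the quadrilateral:
#: high front /i/, high back /u/, low front /æ/, low back /ɑ/.
CORNER_VOWELS = (VowelLabel.IY, VowelLabel.UW, VowelLabel.AE, VowelLabel.AA)

#: Fixed traversal order for the quadrilateral perimeter in the
#: (F2, F1) plane: /i/ -> /æ/ -> /ɑ/ -> /u/ traces the vowel chart
#: without self-intersection for typical formant configurations.
CORNER_ORDER = (VowelLabel.IY, VowelLabel.AE, VowelLabel.AA, VowelLabel.UW)

ALL_VOWELS = tuple(VowelLabel)
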