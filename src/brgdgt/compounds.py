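"""Controlled vocabulary for branched tetraether compound codes.

Branched GDGTs are named by a roman numeral for the number of methyl
branches (I = tetra-, II = penta-, III = hexamethylated) and a letter for
the number of cyclopentane rings (a = 0, b = 1, c = 2).  Positional isomers
methylated at C6 or C7 instead of C5 appear in the literature under three
interchangeable notations: a prime (``IIa'``), a subscript (``IIa_6``), or a
plain suffix (``IIa6``).  The canonical codes here use plain ``6``/``7``
suffixes to avoid unicode ambiguity; readers accept all three notations.
"""

from __future__ import annotations

import re

__all__ = [
    "STANDARD_BRGDGTS",
    "SIX_METHYL",
    "SEVEN_METHYL",
    "UNCOMMON_ISOMERS",
    "BRGTGTS",
    "VOCABULARY",
    "compound_class",
    "normalize_compound_code",
]

#: The nine standard (5-methyl) brGDGTs of the %br denominator.
STANDARD_BRGDGTS = ("Ia", "Ib", "Ic", "IIa", "IIb", "IIc", "IIIa", "IIIb", "IIIc")

#: 6-methyl positional isomers (conventionally primed in the literature).
SIX_METHYL = ("IIa6", "IIb6", "IIc6", "IIIa6", "IIIb6", "IIIc6")

#: 7-methyl positional isomers.
SEVEN_METHYL = ("IIIa7",)

#: Uncommon late-eluting isomers produced under oxygen limitation.
UNCOMMON_ISOMERS = ("IIIa-2", "IIIb-2")

#: Branched glycerol trialkyl glycerol tetraethers (one condensed chain).
BRGTGTS = ("GTGT-Ia", "GTGT-IIa", "GTGT-IIIa-2")

VOCABULARY = STANDARD_BRGDGTS + SIX_METHYL + SEVEN_METHYL + UNCOMMON_ISOMERS + BRGTGTS

_CLASS = {}
for _c in STANDARD_BRGDGTS:
    _CLASS[_c] = "standard-brGDGT"
for _c in SIX_METHYL:
    _CLASS[_c] = "6-methyl"
for _c in SEVEN_METHYL:
    _CLASS[_c] = "7-methyl"
for _c in UNCOMMON_ISOMERS:
    _CLASS[_c] = "uncommon-isomer"
for _c in BRGTGTS:
    _CLASS[_c] = "brGTGT"

# Unicode prime / apostrophe variants that all denote the 6-methyl isomer.
_PRIME_CHARS = "′’ʹ'`"

_GTGT_PREFIX = re.compile(r"^br?gtgt[\s\-_]*", re.IGNORECASE)
_GDGT_PREFIX = re.compile(r"^br?gdgt[\s\-_]*", re.IGNORECASE)
_SUBSCRIPT = re.compile(r"[_\s]([67])$")


def compound_class(code: str) -> str:
    """Return the structural class of a canonical compound code."""
    try:
        return _CLASS[code]
    except KeyError:
        raise ValueError(f"unknown compound code: {code!r}") from None


def normalize_compound_code(raw: str) -> str:
    """Map a raw compound label to its canonical code.

    Handles ``brGDGT``/``brGTGT`` prefixes, unicode and ASCII primes
    (6-methyl), and subscript-style ``_6``/``_7`` suffixes.  Idempotent on
    canonical codes.

    Raises
    ------
    ValueError
        If the token does not resolve to a known compound.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("compound code must be a non-empty string")
    token = raw.strip()
    if token in VOCABULARY:
        return token

    is_gtgt = bool(_GTGT_PREFIX.match(token))
    if is_gtgt:
        token = _GTGT_PREFIX.sub("", token)
    else:
        token = _GDGT_PREFIX.sub("", token)

    for ch in _PRIME_CHARS:
        token = token.replace(ch, "6")
    token = _SUBSCRIPT.sub(r"\1", token)
    # hyphenated isomer suffixes: keep "-2", fold "-6"/"-7" into plain suffix
    m = re.match(r"^(I{1,3}[abc])-([67])$", token)
    if m:
        token = m.group(1) + m.group(2)

    if is_gtgt:
        token = "GTGT-" + token

    if token not in VOCABULARY:
        raise ValueError(f"unknown compound code: {raw!r} (normalized {token!r})")
    return token
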