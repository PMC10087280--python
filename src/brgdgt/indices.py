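"""Lipid-ratio proxy indices computed from a brGDGT profile.

The methylation index MBT'5Me rises with growth/environmental temperature;
the cyclization index CBT5Me is the negative log10 ratio of monocyclic to
acyclic compounds and tracks pH in environmental calibrations; DC is a
linear ring-count alternative.  %br expresses a single compound relative to
the summed nine standard brGDGTs.  Structural-set fractional abundances
normalize each compound among peers of equal ring count (Meth set) or equal
methylation number (Cyc set).

Degenerate inputs (zero denominators, log of zero) yield a flagged
undefined value rather than infinities: the cyclization index is highly
sensitive when the degree of cyclization is small, so degenerate cases must
be explicit, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .compounds import STANDARD_BRGDGTS, VOCABULARY
from .samples import BrgdgtProfile

__all__ = [
    "IndexValue",
    "SetFraction",
    "percent_br",
    "mbt_prime_5me",
    "cbt_5me",
    "dc",
    "structural_set_fractions",
    "tetraether_percent",
    "compute_all_indices",
    "METH_SET",
    "CYC_SET",
    "MBT_NAME",
    "CBT_NAME",
]

MBT_NAME = "MBT'5Me"
CBT_NAME = "CBT5Me"

# Structural-set membership (override via the `membership` argument).
# Meth set: peers share the cyclization letter; 5- and 6-methyl compounds
# are grouped, 7-methyl compounds are excluded by default (their membership
# is not established in the sets' defining scheme).
METH_SET: dict[str, tuple[str, ...]] = {
    "a": ("Ia", "IIa", "IIa6", "IIIa", "IIIa6"),
    "b": ("Ib", "IIb", "IIb6", "IIIb", "IIIb6"),
    "c": ("Ic", "IIc", "IIc6", "IIIc", "IIIc6"),
}

# Cyc set: peers share the methylation numeral.
CYC_SET: dict[str, tuple[str, ...]] = {
    "I": ("Ia", "Ib", "Ic"),
    "II": ("IIa", "IIa6", "IIb", "IIb6", "IIc", "IIc6"),
    "III": ("IIIa", "IIIa6", "IIIb", "IIIb6", "IIIc", "IIIc6"),
}

_MBT_DENOM = ("Ia", "Ib", "Ic", "IIa", "IIb", "IIc", "IIIa")
_DC_DENOM = ("Ia", "Ib", "Ic", "IIa", "IIa6", "IIb", "IIb6")
_DC_NUM = {"Ib": 1.0, "Ic": 2.0, "IIb": 1.0, "IIb6": 1.0}


@dataclass
class IndexValue:
    """A named index value with an explicit definedness flag.

    When ``defined`` is False the ``value`` carries no meaning and must not
    enter regressions; ``reason`` states which degeneracy occurred.
    """

    name: str
    value: float
    defined: bool = True
    reason: str | None = None


@dataclass
class SetFraction:
    """Fractional abundances within the Meth or Cyc structural set."""

    set_name: str
    fractions: dict[str, float] = field(default_factory=dict)

    def get(self, code: str) -> float | None:
        return self.fractions.get(code)


def percent_br(profile: BrgdgtProfile, target: str) -> IndexValue:
    """A compound's abundance as percent of the summed nine standard brGDGTs.

    Targets outside the nine (e.g. the uncommon isomer IIIa-2) are allowed
    and are *not* added to the denominator.
    """
    if target not in VOCABULARY:
        raise ValueError(f"unknown compound code: {target!r}")
    denom = profile.standard_sum()
    name = f"%br({target})"
    if denom <= 0:
        return IndexValue(name, math.nan, defined=False, reason="zero standard-brGDGT sum")
    return IndexValue(name, 100.0 * profile.get(target) / denom)


def mbt_prime_5me(profile: BrgdgtProfile) -> IndexValue:
    """Methylation index of 5-methyl branched tetraethers, in [0, 1].

    (Ia+Ib+Ic) / (Ia+Ib+Ic+IIa+IIb+IIc+IIIa).  6-methyl, 7-methyl, uncommon
    isomers and brGTGTs are excluded.
    """
    denom = sum(profile.get(c) for c in _MBT_DENOM)
    if denom <= 0:
        return IndexValue(MBT_NAME, math.nan, defined=False, reason="zero denominator")
    num = profile.get("Ia") + profile.get("Ib") + profile.get("Ic")
    return IndexValue(MBT_NAME, num / denom)


def cbt_5me(profile: BrgdgtProfile) -> IndexValue:
    """Cyclization index: -log10((Ib+IIb) / (Ia+IIa))."""
    acyclic = profile.get("Ia") + profile.get("IIa")
    cyclized = profile.get("Ib") + profile.get("IIb")
    if acyclic <= 0:
        return IndexValue(CBT_NAME, math.nan, defined=False, reason="zero acyclic sum")
    if cyclized <= 0:
        return IndexValue(CBT_NAME, math.nan, defined=False, reason="no cyclized compounds")
    return IndexValue(CBT_NAME, -math.log10(cyclized / acyclic))


def dc(profile: BrgdgtProfile) -> IndexValue:
    """Degree of cyclization: (Ib + 2*Ic + IIb + IIb6) / (Ia+Ib+Ic+IIa+IIa6+IIb+IIb6)."""
    denom = sum(profile.get(c) for c in _DC_DENOM)
    if denom <= 0:
        return IndexValue("DC", math.nan, defined=False, reason="zero denominator")
    num = sum(w * profile.get(c) for c, w in _DC_NUM.items())
    return IndexValue("DC", num / denom)


def structural_set_fractions(
    profile: BrgdgtProfile,
    set_name: str,
    membership: dict[str, tuple[str, ...]] | None = None,
) -> SetFraction:
    """Fractional abundances within each normalization subset of a structural set.

    ``set_name`` is ``"Meth"`` (normalize among compounds of equal ring
    count) or ``"Cyc"`` (equal methylation number).  Subsets with zero total
    yield no entries.  Pass ``membership`` to override the subset tables.
    """
    if membership is None:
        if set_name == "Meth":
            membership = METH_SET
        elif set_name == "Cyc":
            membership = CYC_SET
        else:
            raise ValueError(f"unknown structural set {set_name!r}; expected Meth or Cyc")
    fractions: dict[str, float] = {}
    for subset in membership.values():
        total = sum(profile.get(c) for c in subset)
        if total <= 0:
            continue
        for c in subset:
            fractions[c] = profile.get(c) / total
    if not fractions:
        raise ValueError(
            f"sample {profile.sample_id!r}: no compounds present in the {set_name} set"
        )
    return SetFraction(set_name, fractions)


def tetraether_percent(profile: BrgdgtProfile) -> IndexValue:
    """Tetraethers as percent of (tetraethers + fatty acids + mono/diethers).

    Tetraethers include all brGDGTs (standard, 6-/7-methyl, uncommon
    isomers) and brGTGTs.
    """
    name = "tetraether%"
    if profile.fa_total is None or profile.mage_total is None or profile.dage_total is None:
        return IndexValue(name, math.nan, defined=False, reason="missing FA/ether totals")
    tet = sum(profile.abundance.values())
    total = tet + profile.fa_total + profile.mage_total + profile.dage_total
    if total <= 0:
        return IndexValue(name, math.nan, defined=False, reason="zero total lipid sum")
    return IndexValue(name, 100.0 * tet / total)


def compute_all_indices(profile: BrgdgtProfile) -> dict[str, IndexValue]:
    """All scalar indices for one profile, keyed by index name."""
    out = {
        MBT_NAME: mbt_prime_5me(profile),
        CBT_NAME: cbt_5me(profile),
        "DC": dc(profile),
        "tetraether%": tetraether_percent(profile),
    }
    for target in ("IIIa-2", "IIIb-2", "Ia", "IIa", "IIIa"):
        iv = percent_br(profile, target)
        out[iv.name] = iv
    return out
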