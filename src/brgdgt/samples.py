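"""Domain containers: lipid profiles, culture and environmental samples, OD curves."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compounds import STANDARD_BRGDGTS, VOCABULARY, normalize_compound_code

__all__ = [
    "BrgdgtProfile",
    "CultureSample",
    "EnvironmentalSample",
    "GrowthCurve",
    "MonthlyTemperatureRecord",
    "ENVIRONMENTAL_SAMPLE_TYPES",
    "TEMPERATURE_PARAMETERS",
]

ENVIRONMENTAL_SAMPLE_TYPES = (
    "soil",
    "peat",
    "lacustrine_sediment",
    "lacustrine_SPM",
    "marine_sediment",
    "bone",
)

#: Registered names for temperature parameters attached to environmental samples.
TEMPERATURE_PARAMETERS = ("MAT", "MAF", "JJA", "WMT", "SST", "water_temp")


@dataclass
class BrgdgtProfile:
    """Per-sample compound abundances over the controlled vocabulary.

    Units are arbitrary but internally consistent within a sample; every
    downstream quantity is a ratio.  Absent compounds are treated as zero.
    ``fa_total``/``mage_total``/``dage_total`` carry fatty-acid, monoether,
    and diether totals in the same units, for the membrane tetraether
    fraction.
    """

    sample_id: str
    abundance: dict[str, float] = field(default_factory=dict)
    fa_total: float | None = None
    mage_total: float | None = None
    dage_total: float | None = None

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for raw, value in self.abundance.items():
            code = raw if raw in VOCABULARY else normalize_compound_code(raw)
            value = float(value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: abundance of {raw!r} must be "
                    f"finite and non-negative, got {value}"
                )
            clean[code] = clean.get(code, 0.0) + value
        self.abundance = clean
        for name in ("fa_total", "mage_total", "dage_total"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(float(v)) or float(v) < 0):
                raise ValueError(f"sample {self.sample_id!r}: {name} must be >= 0")

    def get(self, code: str) -> float:
        """Abundance of a canonical code; absent compounds are 0."""
        return self.abundance.get(code, 0.0)

    def standard_sum(self) -> float:
        """Sum over the nine standard brGDGTs."""
        return sum(self.get(c) for c in STANDARD_BRGDGTS)


@dataclass
class CultureSample:
    """A culture replicate: lipid profile plus growth-condition metadata."""

    profile: BrgdgtProfile
    temperature: float
    ph: float
    o2: float
    replicate: int
    growth_rate: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature) or not math.isfinite(self.o2):
            raise ValueError("temperature and o2 must be finite")
        if not (0.0 < self.ph < 14.0):
            raise ValueError(f"pH must be in (0, 14), got {self.ph}")
        if int(self.replicate) < 1:
            raise ValueError("replicate must be >= 1")
        self.replicate = int(self.replicate)

    @property
    def sample_id(self) -> str:
        return self.profile.sample_id


@dataclass
class EnvironmentalSample:
    """An environmental calibration sample: indices and/or abundances plus metadata."""

    sample_id: str
    sample_type: str
    abundances: dict[str, float] | None = None
    indices: dict[str, float] | None = None
    temperature_params: dict[str, float] = field(default_factory=dict)
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in ENVIRONMENTAL_SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample_type {self.sample_type!r}; expected one of "
                f"{ENVIRONMENTAL_SAMPLE_TYPES}"
            )
        if self.abundances is None and self.indices is None:
            raise ValueError(
                f"sample {self.sample_id!r}: need abundances or precomputed indices"
            )
        for key in self.temperature_params:
            if key not in TEMPERATURE_PARAMETERS:
                raise ValueError(
                    f"unregistered temperature parameter {key!r}; expected one of "
                    f"{TEMPERATURE_PARAMETERS}"
                )


@dataclass
class GrowthCurve:
    """An optical-density time series (times in days, OD unitless)."""

    times: np.ndarray
    od: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od values must be >= 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class MonthlyTemperatureRecord:
    """Mean monthly temperatures for a site: shape (years, 12), degrees C."""

    site_id: str
    monthly_means: np.ndarray
    hemisphere: str = "N"

    def __post_init__(self) -> None:
        self.monthly_means = np.atleast_2d(np.asarray(self.monthly_means, dtype=float))
        if self.monthly_means.shape[1] != 12:
            raise ValueError(
                f"site {self.site_id!r}: need exactly 12 monthly values per year, "
                f"got shape {self.monthly_means.shape}"
            )
        if not np.all(np.isfinite(self.monthly_means)):
            raise ValueError(f"site {self.site_id!r}: monthly means must be finite")
        if self.hemisphere not in ("N", "S"):
            raise ValueError("hemisphere must be 'N' or 'S'")
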