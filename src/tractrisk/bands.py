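"""Five-year age bands and standard-population weights.

The analysis grain for ages is the 18 conventional five-year census bands
(0-4 ... 80-84, 85+). Persons aged 85 and over are pooled; when an exact age
is needed inside that band it is treated as uniform on [85, 100).
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

AGE_BANDS: tuple[str, ...] = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85+",
)

#: Half-open [low, high) age interval for each band; the open-ended 85+ band
#: is capped at 100 for sampling purposes.
BAND_BOUNDS: dict[str, tuple[float, float]] = {
    **{b: (float(b.split("-")[0]), float(b.split("-")[1]) + 1.0)
       for b in AGE_BANDS if b != "85+"},
    "85+": (85.0, 100.0),
}

#: Age above which a person counts as an adult for claims/risk purposes
#: (risk is zeroed at 18 years or younger, so adult means age > 18).
ADULT_AGE = 18.0

# US 2000 projected ("standard million") population distribution over the
# 18 five-year bands, the conventional reference for direct age
# standardization of US mortality rates. Normalized to sum exactly to 1.
_US2000_RAW = {
    "0-4": 0.069135, "5-9": 0.072533, "10-14": 0.073032, "15-19": 0.072169,
    "20-24": 0.066478, "25-29": 0.064530, "30-34": 0.071044, "35-39": 0.080762,
    "40-44": 0.081851, "45-49": 0.072118, "50-54": 0.062716, "55-59": 0.048454,
    "60-64": 0.038793, "65-69": 0.034264, "70-74": 0.031773, "75-79": 0.027000,
    "80-84": 0.017842, "85+": 0.015508,
}
_total = sum(_US2000_RAW.values())
US2000_WEIGHTS: dict[str, float] = {b: v / _total for b, v in _US2000_RAW.items()}

ADULT_BANDS: tuple[str, ...] = tuple(
    b for b in AGE_BANDS if BAND_BOUNDS[b][0] >= 20.0
)


def band_of_age(age) -> np.ndarray:
    """Map ages (scalar or array) to their five-year band label."""
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(ages < 0):
        raise DataError("negative age encountered")
    idx = np.minimum((ages // 5).astype(int), len(AGE_BANDS) - 1)
    return np.asarray(AGE_BANDS, dtype=object)[idx]


def validate_band(label: str) -> str:
    if label not in BAND_BOUNDS:
        raise DataError(f"unknown age band label: {label!r}")
    return label
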