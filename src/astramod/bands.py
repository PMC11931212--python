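"""Five-year age band helpers.

Survey prevalence, disease prevalence and population counts arrive in
5-year age bands; the model runs on integer ages.  Banded inputs are
expanded to single years by constant interpolation within the band, and
ages beyond the oldest band are clamped to it.
"""

from __future__ import annotations

Band = tuple[int, int]

#: Cohort entry bands: 15-19 through 70-74.
DEFAULT_ENTRY_BANDS: tuple[Band, ...] = tuple((lo, lo + 4) for lo in range(15, 75, 5))

#: Grid used for disease prevalence tables: 15-19 through 85-89.
DISEASE_PREV_BANDS: tuple[Band, ...] = tuple((lo, lo + 4) for lo in range(15, 90, 5))

#: Broad bands used for disability weights.
DISABILITY_BANDS: tuple[Band, ...] = ((15, 49), (50, 69), (70, 200))


def format_band(band: Band) -> str:
    lo, hi = band
    if hi >= 150:
        return f"{lo}+"
    return f"{lo}-{hi}"


def parse_band(text: str) -> Band:
    text = text.strip()
    if text.endswith("+"):
        return (int(text[:-1]), 200)
    lo, hi = text.split("-")
    return (int(lo), int(hi))


def band_for_age(age: int, bands: tuple[Band, ...], clamp: bool = True) -> Band:
    """Return the band containing ``age``; clamp to the closest edge band."""
    for band in bands:
        if band[0] <= age <= band[1]:
            return band
    if clamp:
        if age < bands[0][0]:
            return bands[0]
        if age > bands[-1][1]:
            return bands[-1]
    raise KeyError(f"no age band contains age {age}")
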