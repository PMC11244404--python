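"""Canonical EEG frequency bands.

Bands follow the half-open convention ``[lo, hi)`` with the lower edge
inclusive, so the five bands tile 0.5-42 Hz without double-counting the
shared edges at 4, 8, 13 and 30 Hz.
"""

from __future__ import annotations

from .errors import ConfigError

#: Band name -> (lower edge Hz inclusive, upper edge Hz exclusive).
BAND_TABLE: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 42.0),
}

#: Greek aliases accepted anywhere a band name is taken.
_ALIASES = {"δ": "delta", "θ": "theta", "α": "alpha", "β": "beta", "γ": "gamma"}

BAND_NAMES = tuple(BAND_TABLE)


def band_edges(name: str) -> tuple[float, float]:
    """Return ``(lo, hi)`` in Hz for a band name (Greek aliases accepted).

    Raises
    ------
    ConfigError
        If the band name is unknown; the message lists the valid names.
    """
    key = _ALIASES.get(name, name)
    try:
        return BAND_TABLE[key]
    except KeyError:
        raise ConfigError(
            f"unknown band {name!r}; valid bands: {', '.join(BAND_NAMES)}"
        ) from None
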