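"""Frequency-band schemes.

Two dialects coexist in the analysis and both are kept, selected explicitly by
every caller:

* ``sensor`` — the scalp/topography scheme: delta 1–4, theta 4–8, alpha 8–13,
  beta 13–30, gamma 30–60 Hz.  These bands tile the 1–60 Hz reference range,
  so per channel the five relative powers sum to ≈ 1.
* ``source`` — the ROI/source scheme: delta 1–3.5, theta 4–8, alpha 8.5–13,
  beta 13.5–30, gamma 30.5–60 Hz (small guard gaps between bands).
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class BandScheme:
    """Named set of non-overlapping frequency bands."""

    name: str
    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            if lo < hi:
                raise ValueError(f"bands overlap in scheme {self.name!r}")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def __getitem__(self, band: str) -> tuple[float, float]:
        return self.bands[band]


SENSOR_SCHEME = BandScheme(
    "sensor",
    {
        "delta": (1.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 60.0),
    },
)

SOURCE_SCHEME = BandScheme(
    "source",
    {
        "delta": (1.0, 3.5),
        "theta": (4.0, 8.0),
        "alpha": (8.5, 13.0),
        "beta": (13.5, 30.0),
        "gamma": (30.5, 60.0),
    },
)

#: Reference range for relative power (denominator of all band-power ratios).
TOTAL_RANGE = (1.0, 60.0)

#: Alpha band used for frontal alpha asymmetry (sensor dialect).
ALPHA_BAND = SENSOR_SCHEME["alpha"]
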