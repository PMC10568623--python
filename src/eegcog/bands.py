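"""Frequency-band scheme used throughout the pipeline.

The default scheme has eight contiguous, non-overlapping bands covering
1-45 Hz. Band intervals are half-open ``[lo, hi)`` so that a shared edge
(e.g. 4 Hz) is counted in exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 12.0),
    "beta1": (12.0, 15.0),
    "beta2": (15.0, 20.0),
    "beta3": (20.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Ordered name -> (lo, hi) map of analysis bands.

    Invariants: bands are contiguous, non-overlapping and ordered by
    increasing frequency.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        items = list(self.bands.items())
        if not items:
            raise ValueError("band scheme must contain at least one band")
        for name, (lo, hi) in items:
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r}: need 0 < lo < hi, got ({lo}, {hi})")
        for (_, (_, hi_a)), (name_b, (lo_b, _)) in zip(items, items[1:]):
            if abs(hi_a - lo_b) > 1e-12:
                raise ValueError(
                    f"bands must be contiguous; gap/overlap before {name_b!r}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(f"unknown band {name!r}; known: {self.names}") from None

    @property
    def total_range(self) -> tuple[float, float]:
        items = list(self.bands.values())
        return items[0][0], items[-1][1]
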