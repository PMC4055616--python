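"""Canonical region labels for the station groups used throughout.

The eight groups cover a coastal upwelling embayment (Ria de Vigo),
the temperate / oligotrophic / equatorial-upwelling provinces of an Atlantic
meridional transect, and the two Southern Ocean iron-release groups
(inside and outside the fertilised patch).
"""

REGIONS: tuple[str, ...] = (
    "temperate_n",
    "temperate_s",
    "oligotrophic_n",
    "oligotrophic_s",
    "upwelling",
    "coastal",
    "soiree_in",
    "soiree_out",
)

#: Iron-limited Southern Ocean groups: the resource supply index is not
#: meaningful there (growth is iron-, not nitrogen/light-, limited), so these
#: stations are always excluded from RSI analyses.
SOIREE_REGIONS: frozenset[str] = frozenset({"soiree_in", "soiree_out"})

#: The two subtropical-gyre groups, pooled in several analyses.
OLIGOTROPHIC_REGIONS: frozenset[str] = frozenset({"oligotrophic_n", "oligotrophic_s"})

#: The two temperate open-ocean groups.
TEMPERATE_REGIONS: frozenset[str] = frozenset({"temperate_n", "temperate_s"})


def validate_region(label: str) -> str:
    from .errors import ValidationError

    if label not in REGIONS:
        raise ValidationError(
            f"unknown region label {label!r}; expected one of {', '.join(REGIONS)}"
        )
    return label
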