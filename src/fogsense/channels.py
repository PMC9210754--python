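"""Sensor montage: channel identities, canonical ordering, subset parsing.

The montage mirrors a 7-site IMU setup (waist, both thighs, both shanks,
both feet; each site a triaxial accelerometer + triaxial gyroscope) plus
six plantar-pressure (FSR) cells, three per insole: 7*2*3 + 6 = 48
channels in total.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

IMU_LOCATIONS = (
    "waist",
    "left_thigh",
    "right_thigh",
    "left_shank",
    "right_shank",
    "left_foot",
    "right_foot",
)
SOLE_LOCATIONS = (
    "left_sole_1",
    "left_sole_2",
    "left_sole_3",
    "right_sole_1",
    "right_sole_2",
    "right_sole_3",
)
IMU_SENSORS = ("accelerometer", "gyroscope")
AXES = ("x", "y", "z")


@dataclass(frozen=True, order=True)
class ChannelSpec:
    """One physical signal channel: body location, sensor type, axis.

    FSR (plantar pressure) channels are scalar and carry ``axis='none'``.
    """

    location: str
    sensor: str
    axis: str

    def __post_init__(self):
        if self.location in IMU_LOCATIONS:
            if self.sensor not in IMU_SENSORS or self.axis not in AXES:
                raise ConfigError(f"invalid IMU channel {self}")
        elif self.location in SOLE_LOCATIONS:
            if self.sensor != "fsr" or self.axis != "none":
                raise ConfigError(f"invalid sole channel {self}")
        else:
            raise ConfigError(f"unknown location {self.location!r}")

    @property
    def name(self) -> str:
        return f"{self.location}_{self.sensor}_{self.axis}"

    @property
    def is_imu(self) -> bool:
        return self.location in IMU_LOCATIONS


def full_montage() -> list[ChannelSpec]:
    """All 48 channels in canonical order (IMU sites, then sole cells)."""
    chans = [
        ChannelSpec(loc, sen, ax)
        for loc in IMU_LOCATIONS
        for sen in IMU_SENSORS
        for ax in AXES
    ]
    chans += [ChannelSpec(loc, "fsr", "none") for loc in SOLE_LOCATIONS]
    return chans


_MONTAGE_INDEX = {c.name: i for i, c in enumerate(full_montage())}


def montage_order(channels: list[ChannelSpec]) -> list[ChannelSpec]:
    """Sort channels into canonical montage order, dropping duplicates."""
    seen = dict.fromkeys(channels)
    return sorted(seen, key=lambda c: _MONTAGE_INDEX[c.name])


def parse_channel_name(name: str) -> ChannelSpec:
    """Parse a ``<location>_<sensor>_<axis>`` column name."""
    if name not in _MONTAGE_INDEX:
        raise ConfigError(f"unknown channel name {name!r}")
    parts = name.rsplit("_", 2)
    return ChannelSpec(parts[0], parts[1], parts[2])


def expand_subset(tokens: str | list[str]) -> list[ChannelSpec]:
    """Expand a subset specification into montage-ordered channels.

    Accepted tokens: ``all``; a full channel name; ``<site>_<sensor>``
    (e.g. ``left_shank_gyroscope`` -> 3 axes); a bare IMU site (both
    sensors, 6 channels); ``left_sole``/``right_sole`` (3 FSR cells).
    Tokens may be passed as a list or a single comma/plus-separated string.
    """
    if isinstance(tokens, str):
        tokens = [t for t in tokens.replace("+", ",").split(",") if t.strip()]
    out: list[ChannelSpec] = []
    for raw in tokens:
        tok = raw.strip()
        if tok == "all":
            out += full_montage()
        elif tok in _MONTAGE_INDEX:
            out.append(parse_channel_name(tok))
        elif tok in IMU_LOCATIONS:
            out += [ChannelSpec(tok, s, a) for s in IMU_SENSORS for a in AXES]
        elif tok in ("left_sole", "right_sole"):
            side = tok.split("_")[0]
            out += [ChannelSpec(f"{side}_sole_{i}", "fsr", "none") for i in (1, 2, 3)]
        else:
            site_sensor = tuple(
                (loc, sen)
                for loc in IMU_LOCATIONS
                for sen in IMU_SENSORS
                if tok == f"{loc}_{sen}"
            )
            if not site_sensor:
                raise ConfigError(f"unknown channel token {tok!r}")
            loc, sen = site_sensor[0]
            out += [ChannelSpec(loc, sen, a) for a in AXES]
    if not out:
        raise ConfigError("empty channel subset")
    return montage_order(out)


def single_sensor_subsets() -> dict[str, list[ChannelSpec]]:
    """The 16 single-sensor configurations: 7 sites x 2 IMU types + 2 insoles."""
    subsets = {
        f"{loc}_{sen}": expand_subset(f"{loc}_{sen}")
        for loc in IMU_LOCATIONS
        for sen in IMU_SENSORS
    }
    subsets["left_sole"] = expand_subset("left_sole")
    subsets["right_sole"] = expand_subset("right_sole")
    return subsets
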