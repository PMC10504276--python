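"""Raster scan protocols and frame-timing bookkeeping.

Two acquisition schemes are modelled:

* a *block-repeating* raster used for LIV: the lateral field is split into
  ``n_blocks`` blocks of ``locations_per_block`` B-scan locations; each block
  is raster-scanned ``n_repeats`` times with an inter-scan interval of
  ``repeat_interval`` seconds before the scanner moves to the next block, so
  every location sees ``n_repeats`` frames spread over a multi-second window;

* a *fast* raster used for millisecond-scale decorrelation contrast: each
  location is scanned ``n_repeats`` times back-to-back (inter-frame interval
  ``repeat_interval``) before moving on.

Only per-location timestamp sequences are exposed; the within-block frame
interleaving has no downstream effect on the contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RasterProtocol",
    "liv_protocol",
    "fast_protocol",
    "frames_per_volume",
    "time_window",
    "total_acquisition_time",
    "timestamps",
    "lateral_pitch_um",
]


@dataclass(frozen=True)
class RasterProtocol:
    """Scan-timing parameters of a repeated raster protocol.

    Parameters
    ----------
    n_blocks, locations_per_block
        Lateral tiling of the slow axis; total locations is their product.
    a_lines_per_frame
        A-lines per B-scan frame.
    n_repeats
        Frames acquired at each location.
    repeat_interval
        Start-to-start time between successive frames at one location, in
        seconds.
    a_line_rate
        Laser sweep rate in A-lines per second.
    fov_mm
        Lateral field of view per axis in millimetres.
    block_repeating
        True for the LIV-style protocol (repeat each block before moving
        on), False for the fast location-by-location raster.
    """

    n_blocks: int = 4
    locations_per_block: int = 32
    a_lines_per_frame: int = 512
    n_repeats: int = 16
    repeat_interval: float = 0.4096
    a_line_rate: float = 50_000.0
    fov_mm: tuple[float, float] = (3.0, 3.0)
    block_repeating: bool = True

    def __post_init__(self) -> None:
        for name in ("n_blocks", "locations_per_block", "a_lines_per_frame", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        frame_time = self.a_lines_per_frame / self.a_line_rate
        if self.repeat_interval < frame_time:
            raise ValueError(
                f"repeat_interval {self.repeat_interval} s is shorter than one frame "
                f"acquisition ({frame_time} s): a frame cannot outrun itself"
            )
        if self.block_repeating and self.locations_per_block * frame_time > self.repeat_interval:
            raise ValueError(
                "block-repeating protocol: one raster pass over "
                f"{self.locations_per_block} locations takes "
                f"{self.locations_per_block * frame_time} s, longer than the "
                f"{self.repeat_interval} s inter-scan interval"
            )

    @property
    def total_locations(self) -> int:
        return self.n_blocks * self.locations_per_block

    @property
    def frame_time(self) -> float:
        return self.a_lines_per_frame / self.a_line_rate

    def with_(self, **kwargs) -> "RasterProtocol":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def liv_protocol(**overrides) -> RasterProtocol:
    """Default block-repeating protocol: 4 blocks x 32 locations x 16 repeats
    at 409.6 ms, i.e. a 6.144 s observation window per location."""
    return RasterProtocol(block_repeating=True, **overrides)


def fast_protocol(display_rounded: bool = False, **overrides) -> RasterProtocol:
    """Default fast raster: 128 locations x 4 repeats at 12.8 ms.

    With ``display_rounded=True`` the inter-frame interval is the 13 ms
    display figure (window prints as 39 ms); computation elsewhere uses the
    exact 12.8 ms.
    """
    kwargs = dict(
        n_repeats=4,
        repeat_interval=0.013 if display_rounded else 0.0128,
        block_repeating=False,
    )
    kwargs.update(overrides)
    return RasterProtocol(**kwargs)


def frames_per_volume(protocol: RasterProtocol) -> int:
    """Total frames in one volume: blocks x locations/block x repeats."""
    return protocol.total_locations * protocol.n_repeats


def time_window(protocol: RasterProtocol) -> float:
    """Span in seconds from the first to the last frame at one location."""
    if protocol.n_repeats < 2:
        raise ValueError("time window needs n_repeats >= 2")
    return (protocol.n_repeats - 1) * protocol.repeat_interval


def total_acquisition_time(protocol: RasterProtocol) -> float:
    """Wall time to acquire the full volume, in seconds.

    Block-repeating: each block is held for ``n_repeats`` passes of
    ``repeat_interval`` each. Fast raster: every location is held for
    ``n_repeats x repeat_interval``.
    """
    if protocol.block_repeating:
        return protocol.n_blocks * protocol.n_repeats * protocol.repeat_interval
    return protocol.total_locations * protocol.n_repeats * protocol.repeat_interval


def timestamps(protocol: RasterProtocol, location_index: int) -> np.ndarray:
    """Acquisition times of the frames at one slow-axis location.

    An arithmetic sequence with step ``repeat_interval`` offset by the start
    time of the containing block (block-repeating) or of the location itself
    (fast raster). Start-to-start interval convention.
    """
    if not 0 <= location_index < protocol.total_locations:
        raise IndexError(
            f"location_index {location_index} out of range "
            f"[0, {protocol.total_locations})"
        )
    if protocol.block_repeating:
        block = location_index // protocol.locations_per_block
        start = block * protocol.n_repeats * protocol.repeat_interval
    else:
        start = location_index * protocol.n_repeats * protocol.repeat_interval
    return start + protocol.repeat_interval * np.arange(protocol.n_repeats)


def lateral_pitch_um(protocol: RasterProtocol, axis: int = 0) -> float:
    """Lateral pixel pitch in micrometres: FOV / A-lines (fast axis) or
    FOV / total locations (slow axis)."""
    fov_um = protocol.fov_mm[axis] * 1000.0
    n = protocol.a_lines_per_frame if axis == 0 else protocol.total_locations
    return fov_um / n


def timestamp_table(protocol: RasterProtocol) -> np.ndarray:
    """All (location_index, frame_index, t_seconds) rows, for CSV export."""
    rows = []
    for loc in range(protocol.total_locations):
        ts = timestamps(protocol, loc)
        for i, t in enumerate(ts):
            rows.append((loc, i, t))
    return np.array(rows)
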