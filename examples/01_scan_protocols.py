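"""Scan-protocol bookkeeping: the acquisition numbers of both raster modes.

The block-repeating raster gives every B-scan location 16 frames spread over
seconds (slow dynamics, LIV); the fast raster gives 4 frames milliseconds
apart (fast dynamics, complex decorrelation).
"""

from doctk import protocols as SP

liv = SP.liv_protocol()
fast = SP.fast_protocol()
fast_disp = SP.fast_protocol(display_rounded=True)

print("LIV protocol (block-repeating raster)")
print(f"  frames per volume:     {SP.frames_per_volume(liv)}")
print(f"  B-scan locations:      {liv.total_locations}")
print(f"  per-location window:   {SP.time_window(liv):.3f} s")
print(f"  volume acquisition:    {SP.total_acquisition_time(liv):.4f} s")
print("Fast protocol (location-by-location raster)")
print(f"  frames per volume:     {SP.frames_per_volume(fast)}")
print(f"  per-location window:   {SP.time_window(fast)*1000:.1f} ms "
      f"(displayed as {SP.time_window(fast_disp)*1000:.0f} ms)")
print(f"  volume acquisition:    {SP.total_acquisition_time(fast):.4f} s")
print()
print("A 16-frame window of 6.144 s samples second-scale dynamics; the")
print("38.4 ms fast window samples millisecond-scale dynamics.")
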