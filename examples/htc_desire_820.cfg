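# HTC Desire 820 primary camera profile.
# (f, pixel pitch) is the authoritative pair; the horizontal view angle is
# derived internally and is informational only.
focal_length_mm = 3.81
sensor_width_px = 4224
sensor_height_px = 3136
pixel_size_um = 2.377
capture_width_px = 1920
capture_height_px = 1080
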