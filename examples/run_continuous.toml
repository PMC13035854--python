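# Continuous 75-um-disk illumination, 30 s: the run behind the
# continuous-protocol CAR measurement. Omitting [params] uses the
# calibrated defaults shipped with the package.

[grid]
N_r = 192
dr = 1.0

[protocol]
kind = "disk_step"
amplitude = 1.0
diameter = 75.0
w_s = 3.0

[run]
duration = 30.0
save_every = 1.0
safety = 0.4
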