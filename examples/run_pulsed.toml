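# Pulsed recharging protocol: 1 s light / 29 s dark, 30 cycles.

[grid]
N_r = 128
dr = 3.0

[protocol]
kind = "pulse_train"
amplitude = 1.0
diameter = 75.0
w_s = 3.0
t_on = 1.0
t_off = 29.0
n_cyc = 30

[run]
duration = 900.0
save_every = 0.5
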