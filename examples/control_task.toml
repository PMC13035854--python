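# Set-point control task: drive U_r(r0 = 50 um) to -1.5 um along an
# overdamped-spring reference, holding it to the episode end.

[task]
U_goal = -1.5
k_spring = 0.2
r0 = 50.0
dt_control = 1.0
horizon = 30

[policy]
episodes = 400
seed = 1

[grid]
N_r = 64
dr = 3.0
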