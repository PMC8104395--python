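# Packaged default configuration.
#
# Local-circuit couplings carry the standard printed parameterization; the
# long-range profiles p_E / p_I, ambient drives and rate-dependent multiplier
# constants are calibrated defaults frozen by scripts/calibrate_defaults.py
# (synthetic stand-ins satisfying the published structural constraints:
# p_E(0.15) = p_I(0.15) = 1, p_E(1.6) = p_I(1.6) = 0, net-excitatory below the
# d = 0.6 cross-over, net-inhibitory above).

[lattice]
n_hc_per_side = 17
groups_per_hc_side = 7
hc_size = 0.25

[dog]
shape = 4.1
r_in = 0.1
r_out = 0.31
z_norm = 3.62283

[control]
w_6e4e = 0.48

[ambient]
"4E" = 0.012
"4I" = 0.01
"6E" = 0.012
"6I" = 0.01

[longrange]
pe = [
    [0.15, 1.0],
    [0.3, 0.8],
    [0.45, 0.6],
    [0.6, 0.38],
    [0.8, 0.12],
    [1.0, 0.04],
    [1.2, 0.01],
    [1.4, 0.002],
    [1.6, 0.0],
]
pi = [
    [0.15, 1.0],
    [0.3, 0.45],
    [0.45, 0.38],
    [0.6, 0.38],
    [0.8, 0.42],
    [1.0, 0.24],
    [1.2, 0.11],
    [1.4, 0.04],
    [1.6, 0.0],
]

[stimulus]
theta0 = 90.0
radii = "default"

[solver]
tol = 1e-10
nonlinear_tol = 1e-8
damping = 0.5
max_iter = 500

[output]
formats = ["csv"]
png = false

[projections."LGN->4E"]
weight = 0.3
sigma = 0.2
cutoff = 1.0

[projections."LGN->4I"]
weight = 0.25
sigma = 0.2
cutoff = 1.0

[projections."LGN->6E"]
weight = 0.12
sigma = 0.2
cutoff = 1.0

[projections."LGN->6I"]
weight = 0.12
sigma = 0.2
cutoff = 1.0

[projections."4E->4E"]
weight = 1.44
sigma = 0.077
cutoff = 2.0

[projections."4E->4I"]
weight = 0.95
sigma = 0.077
cutoff = 2.0

[projections."4E->6E"]
weight = 0.42
sigma = 0.06
cutoff = 1.0

[projections."4E->6I"]
weight = 0.75
sigma = 0.06
cutoff = 1.0

[projections."4I->4E"]
weight = 0.9
sigma = 0.055
cutoff = 1.5

[projections."4I->4I"]
weight = 0.7
sigma = 0.055
cutoff = 1.5

[projections."6E->4E"]
sigma = 0.07
cutoff = 2.0

[projections."6E->4I"]
weight = 0.81
sigma = 0.07
cutoff = 2.0

[projections."6E->6E"]
weight = 0.94
sigma = 0.075
cutoff = 2.0

[projections."6E->6I"]
weight = 0.96
sigma = 0.075
cutoff = 2.0

[projections."6I->6E"]
weight = 0.7
sigma = 0.05
cutoff = 2.0

[projections."6I->6I"]
weight = 0.7
sigma = 0.05
cutoff = 2.0

[nonlinear]
enabled = false

[[nonlinear.multipliers]]
projection = "6E->4I"
eta_th = 0.24
kappa = 2.0
m_max = 1.2

[[nonlinear.multipliers]]
projection = "4E->4E"
eta_th = 0.32
kappa = 0.2
m_max = 1.02

[[nonlinear.multipliers]]
projection = "6E->6E"
eta_th = 0.26
kappa = 0.2
m_max = 1.02
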