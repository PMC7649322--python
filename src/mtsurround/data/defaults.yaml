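Gescx1: 2.0
Gescx2: 3.0
rho_cx: 0.13
rho_es: 0.3
tau_es: 0.01
Gmtcx: 0.5
Gmtes: 1.0
Gcsmt: 2.0
Gmtmt_ex: 1.0
Gmtmt_inter: 0.1
Gmtmt3: 1.0
phi: 6
T_mt: 0.001
tau_mt: 0.01
T_in: 0.4
M: 49
c_r: 0.2
a: 10.0
b: 2.4
k: 2.0
N: 8
O: 4
f: 1.1
sigma_x: 0.5
sigma_y: 0.5
n_fast: 6
n_slow: 9
tau_g: 0.01
sigma_xc: 0.35
sigma_yc: 0.4
sigma_xs: 0.4
sigma_ys: 0.5
A_c: 1.0
A_s: 0.72
dt: 0.01
deg_per_pixel: 0.25
ms_per_time_unit: 1000.0
apply_rho_es: true
literal_derivative_saturation: false
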