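# Constitutive parameters of the passive stress law, per tissue layer / muscle.
# sigma0, sigma2: stress scale factors (dyn/cm^2); B: exponential rate;
# eps1: strain where the linear term begins; eps2: strain where the
# exponential term begins; sigma_m: maximum isometric active stress
# (dyn/cm^2, muscles only).
name	sigma0	sigma2	B	eps1	eps2	sigma_m
CT	2.2e4	5e4	7.0	-0.9	-0.06	400e4
LCA	3e4	59e4	4.0	-0.9	0.05	140e4
TA	2e4	1.5e4	6.5	-0.9	-0.5	180e4
IA	2e4	30e4	3.5	-0.9	0.0	140e4
PCA	5e4	55e4	5.3	-0.9	0.1	96e4
LIG	2e4	0.15e4	12.8	-0.9	-0.5	nan
SLLP	0.2e4	1.5e4	6.5	-0.9	-0.2	nan
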