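# Heptad position-weight profile for coiled-coil detection.
# Relative residue propensities per heptad register position (a-g), with the
# globular background normalised to ~1. Hydrophobics are favoured at the
# core positions a/d, charged residues at e/g; helix breakers G/P are
# penalised everywhere. Calibrated for this package (see docs/methods.md).
aa	a	b	c	d	e	f	g
L	3.20	0.90	0.90	3.50	0.80	0.90	0.80
I	2.90	0.70	0.70	2.00	0.60	0.70	0.60
V	2.40	0.70	0.70	1.60	0.60	0.70	0.60
M	2.40	0.90	0.90	2.20	0.80	0.90	0.80
F	1.60	0.70	0.70	1.10	0.60	0.70	0.60
A	1.60	1.40	1.40	1.80	1.20	1.30	1.20
Y	1.00	0.80	0.80	0.90	0.70	0.80	0.70
W	0.90	0.60	0.60	0.70	0.50	0.60	0.50
E	1.00	1.60	1.60	0.90	2.20	1.50	2.20
Q	1.10	1.50	1.50	1.00	1.80	1.40	1.80
K	0.90	1.40	1.40	0.80	1.90	1.30	1.90
R	0.90	1.30	1.30	0.80	1.70	1.30	1.70
D	0.60	1.10	1.10	0.50	1.00	1.10	1.00
N	0.80	1.00	1.00	1.40	0.90	1.00	0.90
S	0.70	0.90	0.90	0.70	0.80	0.90	0.80
T	0.70	0.80	0.80	0.70	0.70	0.80	0.70
H	0.70	0.90	0.90	0.60	0.80	0.90	0.80
C	0.80	0.60	0.60	0.70	0.50	0.60	0.50
G	0.30	0.50	0.50	0.25	0.40	0.50	0.40
P	0.10	0.15	0.15	0.10	0.10	0.15	0.10
X	1.00	1.00	1.00	1.00	1.00	1.00	1.00
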