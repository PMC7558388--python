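# Pharmacophore feature perception rules (editable).
# Columns: TYPE <tab> LABEL <tab> PLACEMENT[:length_A] <tab> SMARTS
#
# Placements:
#   atom        feature sits exactly on the matched atom
#   projection  feature sits at the idealized interaction-partner site,
#               length_A along the direction away from the atom's bonded
#               neighbors (default 3.2 A, the canonical heavy-atom
#               hydrogen-bond separation)
#   centroid    feature at the arithmetic centroid of the matched ring atoms
#   normal      two features at +/- length_A along the ring normal through
#               the centroid (pi-stacking partner sites; default 4.0 A)
#   group       atom filter only: matched aliphatic carbons are grouped into
#               chains (>=3 atoms) and non-aromatic carbocycles, one feature
#               per group at the group centroid
POSITIVE	cationic-nitrogen	atom	[N+,n+;!$([N+][O-]);!$([n+][O-])]
DONOR	nh-donor	atom	[#7;!H0]
DONOR	oh-donor	atom	[#8;!H0]
DONOR	nh-donor-proj	projection:3.2	[#7;!H0]
DONOR	oh-donor-proj	projection:3.2	[#8;!H0]
ACCEPTOR	ether-hydroxyl-o	atom	[O;X2;+0]
ACCEPTOR	carbonyl-o	atom	[O;X1]
ACCEPTOR	pyridine-n	atom	[n;X2;+0]
ACCEPTOR	imine-n	atom	[N;X2;+0]
ACCEPTOR	nitrile-n	atom	[N;X1;+0]
ACCEPTOR	amine-n	atom	[N;X3;+0;!$([N][C,S]=[O,S,N]);!$([N]S(=O)=O);!$([N]a)]
ACCEPTOR	ether-hydroxyl-o-proj	projection:3.2	[O;X2;+0]
ACCEPTOR	carbonyl-o-proj	projection:3.2	[O;X1]
ACCEPTOR	pyridine-n-proj	projection:3.2	[n;X2;+0]
ACCEPTOR	imine-n-proj	projection:3.2	[N;X2;+0]
ACCEPTOR	nitrile-n-proj	projection:3.2	[N;X1;+0]
AROMATIC	aromatic-5-ring	centroid	a1aaaa1
AROMATIC	aromatic-6-ring	centroid	a1aaaaa1
AROMATIC	aromatic-7-ring	centroid	a1aaaaaa1
AROMATIC	aromatic-5-ring-stack	normal:4.0	a1aaaa1
AROMATIC	aromatic-6-ring-stack	normal:4.0	a1aaaaa1
AROMATIC	aromatic-7-ring-stack	normal:4.0	a1aaaaaa1
HYDROPHOBIC	aliphatic-carbon	group	[C;X4;+0;!$(C~[!#6;!#1])]
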