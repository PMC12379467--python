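# Stable isotope masses and natural fractional abundances.
# Columns: element, isotope mass (Da), natural abundance, is_label
# (1 marks the designated heavy isotope for SIP labeling of that element).
# Rows per element are ordered by ascending mass; abundances sum to 1.
element	mass	abundance	is_label
H	1.00782503207	0.999885	0
H	2.0141017778	0.000115	1
C	12.0	0.9893	0
C	13.0033548378	0.0107	1
N	14.0030740048	0.99636	0
N	15.0001088982	0.00364	1
O	15.99491461956	0.99757	0
O	16.9991317	0.00038	0
O	17.999161	0.00205	1
S	31.972071	0.9499	0
S	32.97145876	0.0075	0
S	33.9678669	0.0425	0
S	35.96708076	0.0001	0
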