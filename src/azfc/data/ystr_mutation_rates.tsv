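locus	rate_per_generation
DYS19	0.0023
DYS389I	0.0029
DYS390	0.0024
DYS391	0.0026
DYS392	0.0005
DYS393	0.0011
DYS437	0.0013
DYS438	0.0004
DYS439	0.0050
DYS456	0.0044
DYS458	0.0064
DYS460	0.0057
DYS481	0.0050
DYS533	0.0040
DYS635	0.0038
YGATAH4	0.0031
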