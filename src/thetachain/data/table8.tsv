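chain	h_theta_nm	h_theta_err_nm	h_bil_16PC_nm	h_bil_18PC_nm	delta_16PC_printed	delta_18PC_printed
16:0	1.395	0.001	1.503-1.520		7.2-8.2
18:0	1.528	0.001		1.665-1.699		8.3-10.1
18:1(n-9)cis	1.374	0.001	1.532	1.531	10.3	10.3
18:2(n-6)cis	1.293	0.001	1.478	1.491	12.5	13.3
18:3(n-3)cis	1.261	0.001	1.447	1.446	12.8	12.8
18:4(n-3)cis	1.194	0.003	1.398	1.402	14.6	14.8
18:5(n-3)cis	1.165	0.008	1.372	1.373	15.1	15.1
20:4(n-6)cis	1.290	0.002	1.544	1.538	16.5	16.1
20:5(n-3)cis	1.254	0.001	1.497	1.509	16.2	16.9
22:6(n-3)cis	1.328	0.005	1.624	1.645	18.2	19.3
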