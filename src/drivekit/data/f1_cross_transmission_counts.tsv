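# Offspring counts from 18 published experimental crosses in which exactly one
# parent (an F1 or CC hybrid) was heterozygous for the WSB/EiJ high-copy allele
# in the distorted region of mouse chromosome 2.  n_carrier counts offspring
# inheriting the WSB/EiJ allele; printed_tr / printed_p are the values as
# printed in the published table (printed_p from the two-cell chi-square
# goodness-of-fit test of the aggregate counts).
unit_id	role	n_carrier	n_noncarrier	printed_tr	printed_p
cross01	sire	132	136	0.493	8.1e-01
cross02	sire	139	128	0.521	5.0e-01
cross03	sire	263	283	0.482	3.9e-01
cross04	sire	188	171	0.524	3.7e-01
cross05	sire	110	112	0.496	8.9e-01
cross06	sire	98	99	0.498	9.4e-01
cross07	dam	257	274	0.484	4.6e-01
cross08	dam	248	288	0.463	8.4e-02
cross09	dam	127	142	0.472	8.4e-02
cross10	dam	146	122	0.545	3.6e-01
cross11	dam	58	29	0.67	1.4e-01
cross12	dam	135	89	0.6	2.0e-03
cross13	dam	184	111	0.62	2.0e-03
cross14	dam	85	38	0.69	2.0e-05
cross15	dam	130	59	0.69	2.4e-07
cross16	dam	35	4	0.9	6.9e-07
cross17	dam	506	33	0.939	2.9e-92
cross18	dam	512	28	0.948	2.4e-96
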