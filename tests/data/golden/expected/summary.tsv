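metal	known_subunits_total	known_observed	known_meeting_significance	proteins_clustered	clusters_total	clusters_with_known	cover_size	uncovered_peaks
Mo	3	3	3	3	1	1	1	0
Ni	3	3	3	4	1	1	1	0
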