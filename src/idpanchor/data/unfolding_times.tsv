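# Helix unfolding times of the published simulation set for the p53
# N-terminal segment.  Groups: MS = started from the MDM2-bound helix,
# TS = started from the Taz2-bound helix, DS = started disordered (the
# helix is never present, so no unfolding time is defined).
simulation	group	duration_ns	unfolding_time_ns
MS1	MS	100	43
MS2	MS	20	11
MS3	MS	100	42
MS4	MS	100	25
MS5	MS	20	17
MS6	MS	60	28
MS7	MS	20	10
MS8	MS	20	15
MS9	MS	60	23
MS10	MS	60	31
TS1	TS	20	2
TS2	TS	20	4
TS3	TS	20	3
TS4	TS	20	9
TS5	TS	20	8
DS1	DS	50
DS2	DS	50
DS3	DS	50
DS4	DS	50
DS5	DS	50
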