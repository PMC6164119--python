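Assessment	Image	Sample	Baby	Face scale	Progress	85	Time: 10:23:03
Assessment	Image	Sample	Dark room	Face scale	Progress	13	Time: 10:24:48
Assessment	Image	Sample	Spider	Face scale	Progress	22	Time: 10:26:06
Assessment	Image	Sample	Stairs	Face scale	Progress	48	Time: 10:28:55
Assessment	Image	Sample	Boat	Face scale	Progress	79	Time: 10:29:23
Assessment	Image	Sample	Dentist	Face scale	Progress	30	Time: 10:31:01
Assessment	Image	Sample	Door	Face scale	Progress	52	Time: 10:31:53
Assessment	Image	Sample	Wheel	Face scale	Progress	55	Time: 10:32:14
Assessment	Image	Sample	Dog	Face scale	Progress	94	Time: 10:33:23
Rank	Sample Baby	Position 1	Sample Dog	Position 2	Sample Boat	Position 3
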