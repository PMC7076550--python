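name	consensus	stress_related	source_id
ABRE	ACGTG	True	ABRELATERD1
CAAT	CCAAT	True	CAATBOX1
DPBF	ACACNNG	True	DPBFCOREDCDC3
GAGA	GAGAG	True	GAGA8HVBKN3
GBOX	CACGTG	True	GBOXLERBCS
IBOX	GATAAG	True	IBOXCORE
ROOT	ATATT	True	ROOTMOTIFTAPOX1
SEF3	AACCCA	True	SEF3MOTIFGM
SEF4	RTTTTTR	True	SEF4MOTIFGM7S
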