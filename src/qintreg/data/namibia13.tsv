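Zambezi	Kavango
Kavango	Ohangwena
Kavango	Oshikoto
Kavango	Otjozondjupa
Kavango	Omaheke
Ohangwena	Omusati
Ohangwena	Oshana
Ohangwena	Oshikoto
Omusati	Oshana
Omusati	Kunene
Oshana	Oshikoto
Oshikoto	Kunene
Oshikoto	Otjozondjupa
Kunene	Erongo
Kunene	Otjozondjupa
Erongo	Otjozondjupa
Erongo	Khomas
Erongo	Hardap
Otjozondjupa	Omaheke
Otjozondjupa	Khomas
Omaheke	Khomas
Omaheke	Hardap
Khomas	Hardap
Hardap	Karas
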