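# verbatim	standard
emend	aprepitant
aprepitant	aprepitant
fosaprepitant	fosaprepitant
fosaprepitant dimeglumine	fosaprepitant
ivemend	fosaprepitant
netupitant	netupitant
akynzeo	netupitant
netupitant palonosetron	netupitant
ondansetron	ondansetron
dexamethasone	dexamethasone
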