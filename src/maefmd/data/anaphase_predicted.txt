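# Anaphase-promoting module as detected on the DIP yeast network (13 proteins).
Anaphase-promoting	ykl022c ynl172w yfr036w yhr166c ybl084c ylr127c yor249c ygl240w ylr102c ydl008w ydr118w ygl003c ygr225w
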