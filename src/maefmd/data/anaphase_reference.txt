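# The curated anaphase-promoting complex (16 proteins, MIPS-derived benchmark).
Anaphase-promoting	yir025w ydr260c ygl116w yor249c ylr127c ygl240w ylr102c ydl008w ygr225w ydr118w ykl022c yfr036w ygl003c ybl084c yhr166c ynl172w
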