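# Given names used by the surname heuristic: a capitalized token from this
# list immediately before the keyword flags a surname use ("Kara Swisher").
john
kara
mike
michael
sarah
david
anna
james
mary
robert
linda
karen
steve
steven
nick
tom
thomas
emily
jack
laura
chris
christopher
ryan
amanda
brian
jessica
kevin
ashley
eric
megan
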