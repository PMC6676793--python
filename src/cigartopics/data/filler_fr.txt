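# French filler vocabulary for non-English contamination tweets.
je
suis
tres
fatigue
ce
soir
nous
avons
une
bonne
journee
il
fait
beau
aujourdhui
merci
beaucoup
toujours
jamais
avec
mes
amis
demain
encore
cigare
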