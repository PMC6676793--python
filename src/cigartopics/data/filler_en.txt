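# English filler vocabulary for the synthetic-corpus generator. Verified by
# test to be disjoint, after normalization, from every default lexicon
# lemma — so clean synthetic tweets classify exactly as planted.
tonight
later
morning
afternoon
weekend
outside
corner
street
city
music
video
game
phone
coffee
crazy
real
right
back
still
never
ever
today
tomorrow
yesterday
new
old
cool
fresh
long
gas
station
homie
bro
man
deadass
lowkey
fr
bout
finna
gonna
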