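# Validation vocabulary for the suffix lemmatizer: a stripped -ing/-ed/-es
# candidate is accepted only if it appears here. Contains the shipped topic
# lexicon lemmas, common verbs seen in tobacco-related tweet corpora, and
# the synthetic-corpus filler vocabulary.
backwoods
blunt
buy
cherry
crave
damn
enjoy
flavor
fuck
grab
grape
gut
hit
like
love
mango
marijuana
need
pass
pay
peach
pineapple
puff
pumpkin
roll
shit
smoke
strawberry
swisher
try
want
weed
whiteowl
ask
believe
break
bring
burn
call
carry
catch
change
chill
choose
close
come
cop
cough
dip
drink
drive
drop
eat
feel
find
finish
fire
get
give
go
happen
hate
help
hold
keep
know
laugh
learn
leave
light
listen
live
look
lose
make
mean
meet
miss
move
open
pick
play
post
pull
push
put
read
ride
run
say
see
sell
share
show
sip
sit
sleep
speak
spend
stand
start
stay
stop
take
talk
taste
teach
tell
think
turn
twist
use
vibe
wait
walk
watch
wonder
work
wrap
write
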