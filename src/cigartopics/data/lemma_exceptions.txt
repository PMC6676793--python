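# Irregular form -> lemma, whitespace separated, one pair per line.
# A form mapping to itself pins a word against the suffix rules.
bought	buy
brought	bring
caught	catch
taught	teach
thought	think
got	get
gotten	get
went	go
gone	go
done	do
said	say
made	make
took	take
taken	take
came	come
gave	give
given	give
knew	know
known	know
saw	see
seen	see
found	find
felt	feel
kept	keep
left	leave
lost	lose
met	meet
paid	pay
sold	sell
told	tell
wrote	write
written	write
ran	run
ate	eat
eaten	eat
drank	drink
drunk	drink
spoke	speak
spoken	speak
broke	break
broken	break
chose	choose
chosen	choose
lit	light
men	man
women	woman
people	person
children	child
feet	foot
teeth	tooth
# fixed points: words the plain -s rule would mangle
always	always
perhaps	perhaps
besides	besides
news	news
series	series
species	species
jesus	jesus
texas	texas
vegas	vegas
sweets	sweet
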