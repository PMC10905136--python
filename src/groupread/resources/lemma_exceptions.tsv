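# form	lemma
# Irregular inflections and common contractions for the bundled dictionary/rule
# lemmatizer. Values must be fixed points of the lemmatizer itself.
am	be
are	be
is	be
was	be
were	be
been	be
being	be
has	have
had	have
having	have
does	do
did	do
done	do
doing	do
goes	go
went	go
gone	go
going	go
ran	run
running	run
said	say
says	say
saying	say
made	make
making	make
took	take
taken	take
taking	take
came	come
coming	come
saw	see
seen	see
seeing	see
knew	know
known	know
knowing	know
thought	think
thinking	think
got	get
gotten	get
getting	get
gave	give
given	give
giving	give
found	find
finding	find
told	tell
telling	tell
became	become
becoming	become
left	leave
leaving	leave
felt	feel
feeling	feel
brought	bring
bringing	bring
began	begin
begun	begin
beginning	begin
kept	keep
keeping	keep
held	hold
holding	hold
wrote	write
written	write
writing	write
stood	stand
standing	stand
heard	hear
hearing	hear
let	let
meant	mean
meaning	mean
met	meet
meeting	meet
paid	pay
paying	pay
read	read
reading	read
sat	sit
sitting	sit
spoke	speak
spoken	speak
speaking	speak
lay	lie
lain	lie
lying	lie
led	lead
leading	lead
grew	grow
grown	grow
growing	grow
lost	lose
losing	lose
fell	fall
fallen	fall
falling	fall
sent	send
sending	send
built	build
building	build
understood	understand
understanding	understand
drew	draw
drawn	draw
drawing	draw
broke	break
broken	break
breaking	break
spent	spend
spending	spend
cut	cut
rose	rise
risen	rise
rising	rise
drove	drive
driven	drive
driving	drive
bought	buy
buying	buy
wore	wear
worn	wear
wearing	wear
chose	choose
chosen	choose
choosing	choose
ate	eat
eaten	eat
eating	eat
wrote	write
sang	sing
sung	sing
singing	sing
spoke	speak
woke	wake
woken	wake
waking	wake
children	child
men	man
women	woman
people	person
feet	foot
teeth	tooth
mice	mouse
geese	goose
lives	life
wives	wife
knives	knife
leaves	leaf
selves	self
shelves	shelf
halves	half
better	good
best	good
worse	bad
worst	bad
don't	do
doesn't	do
didn't	do
won't	will
wouldn't	would
can't	can
couldn't	could
shouldn't	should
isn't	be
aren't	be
wasn't	be
weren't	be
hasn't	have
haven't	have
hadn't	have
it's	it
that's	that
there's	there
he's	he
she's	she
what's	what
who's	who
i'm	i
i've	i
i'll	i
i'd	i
you're	you
you've	you
we're	we
we've	we
they're	they
they've	they
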