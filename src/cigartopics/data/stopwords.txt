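# English stop-word snapshot, one word per line, "#" comments allowed.
# Curated for tweet surveillance pipelines: function words plus common
# chat interjections. Negations ("no", "not", "don't") and appraisal verbs
# ("like", "love", "need", "want") are deliberately EXCLUDED because
# dictionary-based content analysis keys on them; a test asserts this list
# is disjoint from the shipped topic lexicons.
a
an
the
and
or
but
if
then
than
so
because
as
of
at
by
for
with
about
against
between
into
through
during
before
after
above
below
to
from
up
down
in
out
on
off
over
under
again
further
once
here
there
when
where
why
how
all
any
both
each
few
more
most
other
some
such
only
own
same
too
very
just
can
will
shall
i
im
ive
id
ill
me
my
myself
we
our
ours
ourselves
you
your
yours
yourself
yourselves
u
ur
yall
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
what
which
who
whom
this
that
these
those
am
is
are
was
were
be
been
being
have
has
had
having
do
does
did
doing
would
should
could
cant
wont
aint
hey
hi
oh
ok
okay
lol
lmao
yo
rt
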