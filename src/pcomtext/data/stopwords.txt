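# English stopword list (Snowball-style), filtered for this domain:
# laterality cues (left, right) and negations (no, not, nor) and the
# bilateral cue (both) are deliberately NOT stopwords.
i
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
a
an
the
and
but
if
or
because
as
until
while
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
then
once
here
there
when
where
why
how
all
any
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
so
than
too
very
s
t
can
will
just
don
should
now
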