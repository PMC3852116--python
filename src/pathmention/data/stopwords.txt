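# English closed-class stop-word list used for zero-weighting in TFIDF and
# for stop-word perturbations in the synthetic corpus generator.
a
about
above
after
again
against
all
also
am
among
an
and
any
are
as
at
be
because
been
before
being
below
between
beyond
both
but
by
can
cannot
could
did
do
does
doing
down
during
each
either
et
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
i
if
in
into
is
it
its
itself
just
may
me
might
more
most
must
my
myself
neither
no
nor
not
now
of
off
on
once
only
onto
or
other
our
ours
ourselves
out
over
own
per
same
shall
she
should
since
so
some
such
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
thus
to
too
under
until
up
upon
us
very
via
was
we
were
what
whatever
when
whenever
where
whereas
wherever
whether
which
whichever
while
who
whom
whose
why
will
with
within
without
would
yet
you
your
yours
yourself
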