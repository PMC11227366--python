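# Default surface blacklist: standard English stop words, auxiliary/copular
# verbs, and conjunctions.  Removed from ontology term surfaces at indexing
# time and treated as transparent (non-breaking, non-matching) inside text
# candidates at recognition time.  Override with --blacklist.
# --- stop words (determiners, prepositions, pronouns, particles) ---
a
an
the
of
in
on
at
to
from
by
with
without
for
as
into
onto
upon
over
under
between
among
within
about
above
below
through
during
than
that
this
these
those
it
its
their
his
her
any
all
both
each
some
such
other
more
most
no
not
also
so
then
there
here
when
where
which
who
whom
whose
what
while
per
via
due
# --- auxiliary / copular verbs ---
be
is
are
am
was
were
been
being
have
has
had
having
do
does
did
done
doing
can
could
may
might
must
shall
should
will
would
# --- conjunctions ---
and
or
nor
but
either
neither
if
because
although
though
unless
until
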