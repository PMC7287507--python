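# Default stop-word list: common English function words plus high-frequency
# PubMed title/abstract terms. One term per line; lines starting with '#' are
# comments. Applied only when comparing single words (1-grams) in the lexical
# title-sentence similarity feature and before sentence embedding.
a
about
above
after
again
against
age
aged
all
also
although
among
an
analysis
and
any
are
as
associated
association
at
be
because
been
before
being
below
between
both
but
by
can
cannot
case
cases
patient
patients
clinical
common
compared
conclusion
conclusions
condition
conditions
considered
could
data
day
days
described
did
disease
diseases
do
does
done
due
during
each
early
effect
effects
et
evaluated
evaluation
evidence
few
findings
first
five
following
for
found
four
from
further
group
groups
had
has
have
having
he
her
here
high
higher
him
his
how
however
identified
if
important
in
include
included
including
increased
into
is
it
its
large
later
less
level
levels
like
low
lower
made
main
male
female
many
may
method
methods
might
more
most
much
must
new
no
non
nor
not
noted
observed
of
often
on
one
only
or
other
others
our
out
over
own
paper
part
performed
population
possible
present
presence
presented
previous
previously
rare
rarely
rate
recent
related
report
reported
reports
respectively
result
results
review
risk
same
second
seen
several
she
should
showed
shown
significant
significantly
since
six
small
so
some
state
studies
study
such
than
that
the
their
them
then
there
therefore
these
they
this
those
three
through
time
to
total
treated
treatment
two
under
until
up
upon
use
used
using
value
values
various
very
was
we
well
were
what
when
where
whether
which
while
who
whose
with
within
without
would
year
years
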