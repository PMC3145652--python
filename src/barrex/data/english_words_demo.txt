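# Small demonstration English word list (one word per line, case-insensitive).
# Stands in for a full spell-checker word library; point `load_word_list` at a
# complete installation (e.g. a SCOWL build) for real screening runs.
a
about
all
also
an
and
are
as
at
be
been
both
but
by
can
cast
cell
cells
compared
data
each
expression
figure
for
from
gene
genes
gast
groups
had
has
have
here
in
increased
is
it
its
levels
mast
may
men
method
methods
more
most
much
no
normal
not
of
on
one
only
or
other
our
rest
results
samples
she
set
shown
some
study
studies
table
than
that
the
their
then
there
these
this
those
three
tissue
tissues
to
two
used
was
we
were
when
which
while
with
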