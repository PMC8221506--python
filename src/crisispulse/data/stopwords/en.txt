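# English stopwords (transliterated ASCII)
a
an
the
and
or
but
if
of
to
in
on
at
for
with
is
are
was
were
be
been
it
its
this
that
these
those
i
you
he
she
we
they
not
no
so
as
by
from
have
has
had
do
does
did
will
would
can
could
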