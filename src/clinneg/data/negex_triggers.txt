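# Default trigger lexicon for the rule-based negation baseline.
# Four sections; one phrase per line; '#' starts a comment.
# Compiled from the publicly distributed NegEx trigger lists; entries are
# data, not code — edit freely, per-corpus customization of rules is
# usually necessary.

[pre_negation]
no
not
without
denies
denied
deny
no evidence of
no evidence for
no sign of
no signs of
no suggestion of
absence of
absent
negative for
never had
never developed
free of
rules out
rule out
ruled out
rule him out
rule her out
with no
no complaints of
no new
lack of
lacks
no history of
fails to reveal
declines
declined
unremarkable for
cannot see
no cause of
resolved
patient was not
checked for
evaluate for
test for
to exclude

[post_negation]
was ruled out
were ruled out
is ruled out
are ruled out
has been ruled out
have been ruled out
be ruled out
unlikely
was negative
were negative
are negative
is negative
was not found
non diagnostic
free

[pseudo_negation]
no increase
no change
no definite change
no interval change
no significant change
no significant interval change
no suspicious change
no further
not extend
not cause
not certain if
not certain whether
not necessarily
not only
not rule out
not ruled out
not been ruled out
gram negative
without difficulty
no newly identified

[termination]
but
however
although
though
yet
nevertheless
aside from
apart from
except
cause for
cause of
causes for
causes of
etiology for
etiology of
origin for
origin of
reason for
reason of
reasons for
reasons of
secondary to
as a cause of
as a cause for
as a reason of
as a reason for
which
who
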