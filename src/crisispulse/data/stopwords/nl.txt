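# Dutch stopwords (transliterated ASCII)
de
het
een
en
of
maar
als
van
naar
in
op
aan
voor
met
is
zijn
was
waren
worden
wordt
werd
het
dit
dat
deze
die
ik
jij
je
hij
zij
ze
wij
we
jullie
niet
geen
zo
als
door
uit
hebben
heeft
had
doen
doet
deed
zal
zou
kan
kon
na
bij
om
tot
over
onder
tegen
zonder
sinds
ja
nee
alle
alles
iets
niets
zeer
hier
daar
nu
vandaag
ook
nog
al
wel
dan
toch
meer
men
mij
me
jou
ons
hun
hen
er
toen
wat
hoe
waarom
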