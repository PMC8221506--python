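# German stopwords (transliterated ASCII)
der
die
das
und
oder
aber
wenn
von
zu
in
im
auf
an
fuer
mit
ist
sind
war
waren
sein
es
ein
eine
einer
einem
einen
dies
diese
dieser
dieses
ich
du
er
sie
wir
ihr
nicht
kein
so
als
durch
aus
haben
hat
hatte
tun
wird
werden
wuerde
kann
koennte
nach
bei
um
am
dem
den
des
was
wie
noch
nur
auch
schon
da
dann
doch
mehr
man
mich
mir
dich
dir
uns
euch
ueber
unter
vor
zwischen
gegen
ohne
bis
seit
ja
nein
alle
alles
etwas
nichts
sehr
hier
dort
jetzt
heute
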