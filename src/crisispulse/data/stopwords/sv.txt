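# Swedish stopwords (transliterated ASCII)
och
det
att
i
en
jag
hon
som
han
paa
den
med
var
sig
foer
saa
till
aer
men
ett
om
hade
de
av
icke
mig
du
henne
daa
sin
nu
har
inte
hans
honom
skulle
hennes
daer
min
man
ej
vid
kunde
naagot
fraan
ut
naer
efter
upp
vi
dem
vara
vad
oever
aen
dig
kan
sina
haer
ha
mot
alla
under
naagon
eller
allt
mycket
sedan
ju
denna
sjaelv
detta
aat
utan
varit
hur
ingen
mitt
ni
bli
blev
oss
din
dessa
naagra
deras
blir
mina
samma
vilken
er
saadan
vaar
blivit
dess
inom
mellan
saadant
varfoer
varje
vilka
ditt
vem
vilket
sitta
saadana
vart
dina
vars
vaart
vaara
ert
era
vilkas
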