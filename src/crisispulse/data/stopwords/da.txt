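# Danish stopwords (transliterated ASCII)
og
i
jeg
det
at
en
den
til
er
som
paa
de
med
han
af
for
ikke
der
var
mig
sig
men
et
har
om
vi
min
havde
ham
hun
nu
over
da
fra
du
ud
sin
dem
os
op
man
hans
hvor
eller
hvad
skal
selv
her
alle
vil
blev
kunne
ind
naar
vaere
dog
noget
ville
jo
deres
efter
ned
skulle
denne
end
dette
mit
ogsaa
under
have
dig
anden
hende
mine
alt
meget
sit
sine
vor
mod
disse
hvis
din
nogle
hos
blive
mange
ad
bliver
hendes
vaeret
thi
jer
saadan
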