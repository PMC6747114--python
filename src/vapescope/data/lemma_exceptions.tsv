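# surface<TAB>lemma — consulted before the suffix rules.
vaping	vape
vaped	vape
vapes	vape
vapers	vaper
juuling	juul
juuled	juul
juuls	juul
driving	drive
drives	drive
drove	drive
driven	drive
buses	bus
busses	bus
gases	gas
smoking	smoke
smoked	smoke
smokes	smoke
taking	take
making	make
coming	come
having	have
using	use
being	be
giving	give
bought	buy
went	go
children	child
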