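# miRBase species prefix -> plant clade/family, used for conservation
# classification. User-overridable via --clade-map / load_clade_map().
ath	Brassicaceae
aly	Brassicaceae
bra	Brassicaceae
bol	Brassicaceae
osa	Poaceae
tae	Poaceae
zma	Poaceae
bdi	Poaceae
sbi	Poaceae
hvu	Poaceae
gma	Fabaceae
mtr	Fabaceae
lja	Fabaceae
pvu	Fabaceae
atr	Amborellaceae
vvi	Vitaceae
sly	Solanaceae
stu	Solanaceae
nta	Solanaceae
ptc	Salicaceae
ppe	Rosaceae
mdm	Rosaceae
ppt	Funariaceae
smo	Selaginellaceae
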