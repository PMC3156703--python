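source	target	sign	note
speract	speract	activating	constant external stimulus (self-input)
speract	SR	activating	speract binds its flagellar receptor
SR	GC	activating	the bound receptor stimulates membrane guanylate cyclase
GC	cGMP	activating	guanylate cyclase produces cGMP
cGMP	KCNG	activating	cGMP opens the cGMP-gated K+ channel
KCNG	dK	activating	open KCNG raises K+ permeability
CaKC	dK	activating	open CaKC raises K+ permeability
dK	V	inhibiting (hyperpolarizing)	K+ efflux hyperpolarizes the membrane
CaKC	V	inhibiting (hyperpolarizing)	Ca-activated K+ current hyperpolarizes
dCl	V	inhibiting (hyperpolarizing)	Cl- current opposes depolarization
HCN	V	activating (depolarizing)	HCN inward current repolarizes/depolarizes
cAMPCC	V	activating (depolarizing)	cAMP-gated cation/Ca2+ current depolarizes
LVA	V	activating (depolarizing)	open low-threshold Ca2+ channel depolarizes
HVA	V	activating (depolarizing)	open high-threshold Ca2+ channel depolarizes
V	V	voltage-conditional	current potential level (state persistence)
speract	V	activating (depolarizing)	weak constitutive receptor current while speract is bound
V	NCE	voltage-conditional	hyperpolarization activates Na+/Ca2+ exchange
V	NHE	voltage-conditional	hyperpolarization activates Na+/H+ exchange
NHE	pHi	activating	Na+/H+ exchange alkalinizes the flagellum
pHi	sAC	activating	alkalinization stimulates soluble adenylate cyclase
sAC	cAMP	activating	soluble adenylate cyclase produces cAMP
PDE	cAMP	inhibiting	phosphodiesterase hydrolyzes cAMP (dominant)
cAMP	cAMP	activating	cAMP self-maintenance (documented self-input)
speract	PDE	activating	phosphodiesterase is available while the pathway is engaged
V	HCN	voltage-conditional	hyperpolarization activates HCN
cGMP	HCN	activating	cyclic-nucleotide requirement of HCN gating
cAMP	HCN	activating	cAMP facilitates HCN
cAMP	cAMPCC	activating	cAMP gates the cAMP-dependent Ca2+ channel
V	HVA	voltage-conditional	hyperpolarization removes inactivation; depolarization opens
Ca	HVA	inhibiting	calcium-dependent inactivation/block
cAMP	HVA	activating	cAMP/PKA facilitation of channel availability
HVA	HVA	activating	channel state persistence (self-input)
V	LVA	voltage-conditional	hyperpolarization primes; release opens (rebound)
Ca	LVA	inhibiting	calcium gates recovery from inactivation
LVA	LVA	activating	channel state persistence (self-input)
pHi	LVA	activating	alkalinization primes the low-threshold window current
LVA	Ca	activating	Ca2+ influx through open LVA
HVA	Ca	activating	Ca2+ influx through open HVA
Ca	Ca	activating	concentration persistence (self-input)
speract	Ca	activating	speract-dependent tonic influx
NCE	Ca	inhibiting	Na+/Ca2+ exchange extrudes Ca2+
CaP	Ca	inhibiting	constitutive Ca2+ pump extrusion
cAMPCC	Ca	activating	Ca2+ influx through the cAMP-gated channel
Ca	CaCC	activating	supratonic Ca2+ opens the Ca-activated Cl- channel
Ca	CaKC	activating	elevated Ca2+ opens the Ca-activated K+ channel
V	CaKC	voltage-conditional	CaKC opens on depolarization
CaP	CaP	activating	constitutive pump activity (self-input)
CaCC	dCl	activating	open CaCC raises Cl- permeability
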