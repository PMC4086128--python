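# Default blocklist of non-biological ligands: crystallization additives,
# cryoprotectants and buffer components that appear as HETATM groups but
# are not functional binders.  One chemical component code per line;
# override with --blocklist.
SO4   # sulphate ion
PO4   # phosphate ion
GOL   # glycerol
PEG   # di(hydroxyethyl)ether
PG4   # tetraethylene glycol
P6G   # hexaethylene glycol
1PE   # pentaethylene glycol
EDO   # ethylene glycol
MPD   # 2-methyl-2,4-pentanediol
DMS   # dimethyl sulfoxide
ACT   # acetate
ACY   # acetic acid
FMT   # formate
TRS   # tris buffer
MES   # MES buffer
EPE   # HEPES buffer
CIT   # citrate
FLC   # citrate anion
TLA   # tartrate
MLI   # malonate
CAC   # cacodylate
BME   # beta-mercaptoethanol
DTT   # dithiothreitol
IMD   # imidazole
NO3   # nitrate
SCN   # thiocyanate
AZI   # azide
BCT   # bicarbonate
CO3   # carbonate
EOH   # ethanol
IPA   # isopropanol
MOH   # methanol
PGE   # triethylene glycol
DIO   # dioxane
URE   # urea
BOG   # octyl glucoside (detergent)
LDA   # lauryl dimethylamine oxide (detergent)
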