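"""Reference protein backbone sequences (public UniProt entries).

Only the small set of backbones needed by the bundled presets is stored;
arbitrary sequences are supported through
:func:`glycosim.proteoforms.backbone_mass_from_sequence`.
"""

#: Mature human erythropoietin chain, UniProt P01588 residues 28-192.
#: The C-terminal Arg166 of the full mature chain is removed in the
#: circulating/therapeutic form (des-Arg166), leaving 165 residues.
#: Two disulfide bridges (C7-C161, C29-C33 in mature numbering).
RHEPO_MATURE_DES_ARG166 = (
    "APPRLICDSRVLERYLLEAKEAENITTGCAEHCSLNENITVPDTKVNFYAWKRMEVGQQAVEVWQGLALLSE"
    "AVLRGQALLVNSSQPWEPLQLHVDKAVSGLRSLTTLLRALGAQKEAISPPDAASAAPLRTITADTFRKLFRV"
    "YSNFLRGKLKLYTGEACRTGD"
)

RHEPO_N_DISULFIDES = 2

#: rhEPO backbone average mass as conventionally reported for the
#: des-Arg166 chain with both disulfides formed, in Da.
RHEPO_BACKBONE_MASS = 18235.99
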