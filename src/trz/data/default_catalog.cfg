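# Default tRNase Z motif catalog.
#
# Pattern notation: uppercase letter = exact residue, lowercase 'x' = any
# residue, [ABC] = any listed residue.  Ranks give the canonical N->C order
# of the architectural slots:
#   1 PxKxRN / EGxSxxG   (amino side of Motif I)
#   2 Motif I            3 Motif II (His motif)
#   4 flexible-arm motif (KL or GP)
#   5 Motif III          6 Motif IV
#   7 HEAT / xExT        8 Motif V
#   9 HST / HxH
#
# Motifs I, III, IV and V carry no explicit consensus beyond their invariant
# Asp/His; the minimal anchored patterns below are placeholders refinable
# from family alignments, and are constrained by a window (max gap, in
# residues, to the preceding placed motif) to suppress spurious hits.
# Pseudo-motifs reuse the parent pattern with a raised mismatch budget and a
# forced mismatch at the catalytically critical position.

[motifs]
# name          pattern                 mm  rank  options
PXKXRN          Px[KL]xRN               0   1     critical=2
EGXSXXG         EGxSxxG                 1   1     critical=0
MOTIF_I         xxDx                    0   2     window=60 critical=2
MOTIF_II        HxHxDH                  0   3     critical=2
KL              KLKxxYxxLxGxxIxxLK      1   4     critical=0
GP              GxPxGP                  0   4     critical=2
MOTIF_III       xHxx                    0   5     window=80 critical=1
MOTIF_IV        xDxx                    0   6     window=60 critical=1
HEAT            HEAT                    1   7     critical=0
XEXT            [TMVL]E[SAMTCA]T        0   7     critical=1
MOTIF_V         xHxx                    0   8     window=60 critical=1
HST             HST                     0   9     critical=0
HXH             H[TS]H                  0   9     critical=0
PSEUDO_PXKXRN   Px[KL]xRN               2   1     forced=2
PSEUDO_I        xxDx                    2   2     forced=2 window=60
PSEUDO_II       HxHxDH                  2   3     forced=4

[architecture TM_S]
required = EGXSXXG MOTIF_I MOTIF_II KL MOTIF_III MOTIF_IV XEXT MOTIF_V HXH
optional =

[architecture BACTERIAL_S]
required = PXKXRN MOTIF_I MOTIF_II GP MOTIF_III MOTIF_IV HEAT MOTIF_V HST
optional =

[architecture EUKARYOTIC_L_N]
required = PSEUDO_PXKXRN PSEUDO_I PSEUDO_II GP
optional =

[architecture EUKARYOTIC_L_C]
required = PXKXRN MOTIF_I MOTIF_II MOTIF_III MOTIF_IV HEAT MOTIF_V HST
optional =
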