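# CTL observations used to select the logical parameters of the mTOR BRN.
# 1: from the all-off state the network can return to the all-off expression
#    pattern after at least one step (homeostatic recurrence).
(PI3K = 0 & FOXO = 0 & mTORC2 = 0 & Akt = 0 & mTORC1 = 0 & PTEN = 0) -> (EX(EF(PI3K = 0 & FOXO = 0 & mTORC2 = 0 & Akt = 0 & mTORC1 = 0)))
# 2: loss of the tumor suppressors can trap the system in the proliferative
#    deadlock with Akt/mTORC1/mTORC2/PI3K on and PTEN/FOXO off.
(PTEN = 1 & FOXO = 1 & Akt = 0 & PI3K = 1 & mTORC1 = 1 & mTORC2 = 1) -> (EF(AG(Akt = 1 & PTEN = 0 & FOXO = 0 & mTORC1 = 1 & mTORC2 = 1 & PI3K = 1)))
# 3: sustained PI3K/Akt/mTORC1 signalling can lead to permanent loss of
#    PTEN and FOXO expression.
(PI3K = 1 & FOXO = 0 & Akt = 1 & mTORC1 = 1) -> (EF(AG(Akt = 1 & FOXO = 0 & PTEN = 0)))
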