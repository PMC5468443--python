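# Delay constraints reported for the invariance kernel of the homeostatic
# mTOR cycle (pi(X) abbreviates dX+ + dX-, the period of entity X).
# This file is an example input for relation-matrix analysis of a
# user-supplied constraint set; the pipeline itself recomputes the kernel
# from the cycle.
dFOXO+ <= dmTORC1- + dAkt-
dFOXO- <= dAkt+ + dmTORC1+
dPI3K- <= dmTORC1+ + dAkt-
pi(FOXO) + dPI3K- <= pi(Akt) + pi(mTORC1)
pi(FOXO) + pi(PI3K) <= pi(Akt) + pi(mTORC1) + dmTORC2+
dFOXO+ + dPI3K- <= pi(mTORC1) + dAkt-
pi(FOXO) + pi(PI3K) <= pi(mTORC2) + dAkt+ + dmTORC1+
dPI3K+ + dFOXO+ <= dAkt+ + pi(mTORC2)
pi(PI3K) + dFOXO+ <= dAkt+ + pi(mTORC2) + dmTORC1+
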