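Reference PDB coordinate files (e.g. `2CZT.pdb`, `1JGJ.pdb`, `1IJD.pdb`,
`1AX8.pdb`, `3OZ6.pdb`, `4HW7.pdb`) belong here if you want the structural
baseline checks and `scripts/acceptance.py` to report the mean pairwise
Calpha distance of each entry. The coordinates are not distributed with the
package; download them from the Protein Data Bank (https://www.rcsb.org)
and drop the `.pdb` files into this directory.
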