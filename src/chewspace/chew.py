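"""Published residue subsets and entry identifiers for the CheW case study.

CheW is the coupling protein of the bacterial chemotaxis signalling complex,
linking chemoreceptors (MCPs) to the CheA kinase.  Solution-NMR ensembles of
20 models each exist for the *T. maritima* protein (PDB 1K0S, 151 residues,
UniProt Q56311) and the *E. coli* protein (PDB 2HO9, 167 residues, UniProt
P0A964).  The subsets below are the standard selections used when comparing
those ensembles with homology models:

``*_ALL``
    every residue of the chain;
``*_CORE``
    the structured core, excluding the flexible N- and C-terminal tails
    (*E. coli*: residues 17–157; *T. maritima*: residues 10–147);
``*_AB_CONSENSUS``
    the α/β consensus residues — residues adopting helix or strand in all 20
    NMR models, the most structurally conserved subset;
``*_ALIGNED``
    the residues of each organism that align without gaps in the pairwise
    *E. coli* / *T. maritima* sequence alignment, used as the fitting frame
    for cross-organism ensemble comparisons.

All numbers are in the deposited PDB numbering (1-based).
"""

from __future__ import annotations

from .subsets import ResidueSubsetSpec

__all__ = [
    "ECOLI_N_RESIDUES",
    "TM_N_RESIDUES",
    "ECOLI_ALL",
    "TM_ALL",
    "ECOLI_CORE",
    "TM_CORE",
    "ECOLI_AB_CONSENSUS",
    "TM_AB_CONSENSUS",
    "ECOLI_ALIGNED",
    "TM_ALIGNED",
    "PDB_ENTRIES",
    "UNIPROT_ENTRIES",
]

#: Chain lengths of the deposited CheW constructs.
ECOLI_N_RESIDUES = 167
TM_N_RESIDUES = 151

#: PDB / UniProt identifiers of the two CheW entries.
PDB_ENTRIES = {"ecoli": "2HO9", "tmaritima": "1K0S"}
UNIPROT_ENTRIES = {"ecoli": "P0A964", "tmaritima": "Q56311"}

ECOLI_ALL = ResidueSubsetSpec("ecoli_all", ((1, ECOLI_N_RESIDUES),), "backbone")
TM_ALL = ResidueSubsetSpec("tm_all", ((1, TM_N_RESIDUES),), "backbone")

#: Structured core: tails 1–16 / 158–167 (E. coli) and 1–9 / 148–151
#: (T. maritima) excluded.
ECOLI_CORE = ResidueSubsetSpec("ecoli_core", ((17, 157),), "backbone")
TM_CORE = ResidueSubsetSpec("tm_core", ((10, 147),), "backbone")

#: α/β consensus residues: helix or strand in all 20 NMR models.
ECOLI_AB_CONSENSUS = ResidueSubsetSpec.from_text(
    "ecoli_ab_consensus",
    "17-19,22-24,27-30,36-39,57-61,64-69,87-93,96-102,104-105,109-111,"
    "133-135,142-144,154-160",
    "backbone",
)
TM_AB_CONSENSUS = ResidueSubsetSpec.from_text(
    "tm_ab_consensus",
    "12-17,22-26,30-34,51-55,58-63,65-69,80-84,92-95,97-103,127,132,"
    "134-135,139-147",
    "backbone",
)

#: Residues aligning without gaps in the pairwise E. coli / T. maritima
#: alignment (the fitting frame for cross-organism comparisons).
ECOLI_ALIGNED = ResidueSubsetSpec.from_text(
    "ecoli_aligned", "7-72,74-120,123-151,154-161", "backbone"
)
TM_ALIGNED = ResidueSubsetSpec.from_text("tm_aligned", "1-150", "backbone")
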