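"""Reference data for the VEGF-A mRNA construct used throughout the package.

The construct is a chemically modified (5meC, pseudouridine), CleanCap'd and
polyadenylated mRNA of 852 nt whose coding region is the 576-nt VEGF-A 165
CDS below (start and stop codons included), encoding a 191-aa protein.
Only the CDS and the protein sequence are available; the UTRs and poly(A)
tail are proprietary to the construct vendor, so the full-length molecular
weight cannot be computed from sequence.  ``FULL_LENGTH_MW`` is therefore a
derived constant, back-solved from the administered dose of 3 ug equalling
6.5e12 copies; callers may override it wherever a molecular weight is taken.
"""

from __future__ import annotations

from .seqchem import ProteinSequence, RnaSequence

__all__ = [
    "VEGFA_CDS",
    "VEGFA_PROTEIN",
    "CDS_LENGTH_NT",
    "PROTEIN_LENGTH_AA",
    "PROTEIN_MW_KDA",
    "FULL_LENGTH_MW",
    "FULL_LENGTH_NT",
    "DOSE_MRNA_G",
    "DOSE_COPIES",
    "LNPS_PER_DOSE",
    "COPIES_PER_LNP",
]

_CDS = (
    "AUGAACUUUCUGCUGUCUUGGGUGCAUUGGAGCCUUGCCUUGCUGCUCUACCUCCACCAUGCCAAGUGGU"
    "CCCAGGCUGCACCCAUGGCAGAAGGAGGAGGGCAGAAUCAUCACGAAGUGGUGAAGUUCAUGGAUGUCUA"
    "UCAGCGCAGCUACUGCCAUCCAAUCGAGACCCUGGUGGACAUCUUCCAGGAGUACCCUGAUGAGAUCGAG"
    "UACAUCUUCAAGCCAUCCUGUGUGCCCCUGAUGCGAUGCGGGGGCUGCUGCAAUGACGAGGGCCUGGAGU"
    "GUGUGCCCACUGAGGAGUCCAACAUCACCAUGCAGAUUAUGCGGAUCAAACCUCACCAAGGCCAGCACAU"
    "AGGAGAGAUGAGCUUCCUACAGCACAACAAAUGUGAAUGCAGACCAAAGAAAGAUAGAGCAAGACAAGAA"
    "AAUCCCUGUGGGCCUUGCUCAGAGCGGAGAAAGCAUUUGUUUGUACAAGAUCCGCAGACGUGUAAAUGUU"
    "CCUGCAAAAACACAGACUCGCGUUGCAAGGCGAGGCAGCUUGAGUUAAACGAACGUACUUGCAGAUGUGA"
    "CAAGCCGAGGCGGUGA"
)

_PROTEIN = (
    "MNFLLSWVHWSLALLLYLHHAKWSQAAPMAEGGGQNHHEVVKFMDVYQRSYCHPIETLVDIFQEYPDEIE"
    "YIFKPSCVPLMRCGGCCNDEGLECVPTEESNITMQIMRIKPHQGQHIGEMSFLQHNKCECRPKKDRARQE"
    "NPCGPCSERRKHLFVQDPQTCKCSCKNTDSRCKARQLELNERTCRCDKPRR"
)

#: 576-nt VEGF-A 165 CDS (sense strand), start and stop codons included.
VEGFA_CDS = RnaSequence(name="VEGFA_CDS", residues=_CDS)

#: The 191-aa VEGF-A protein encoded by the CDS (stop codon excluded).
VEGFA_PROTEIN = ProteinSequence(name="VEGFA", residues=_PROTEIN)

CDS_LENGTH_NT = 576
PROTEIN_LENGTH_AA = 191

#: Reported average molecular weight of the 191-aa protein, kDa.
PROTEIN_MW_KDA = 22.31364

#: Length of the full capped/polyadenylated construct, nt.
FULL_LENGTH_NT = 852

#: Molecular weight of the full-length construct, g/mol.  DERIVED, not a
#: sequence computation: back-solved from 3 ug of mRNA == 6.5e12 copies
#: (3e-6 g / 277900 g/mol * N_A = 6.50e12).  Override where appropriate.
FULL_LENGTH_MW = 277_900.0

#: Standard in vitro dose: 3 ug of mRNA delivered per replicate.
DOSE_MRNA_G = 3e-6

#: Copy number of the standard dose at FULL_LENGTH_MW.
DOSE_COPIES = 6.5e12

#: Particle count carrying the standard dose.
LNPS_PER_DOSE = 2.5e11

#: Payload calibration of the formulation: mRNA copies per particle.
COPIES_PER_LNP = 26.0
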