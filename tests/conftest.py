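"""Shared fixtures: reference ranked tables and small count fixtures.

``REFERENCE_DOWN`` / ``REFERENCE_UP`` are the published top-20 annotated
transcript tables of a two-library light-induction experiment (competent
vs light-induced plasmodia; library totals 125,456 and 99,632 reads),
used as input data: (contig_id, accession, description, hits_d, hits_l,
tabulated p-value).  The tabulated p-values serve as external validation
values for the conditional count test.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dgekit.acdge import LibraryPair

REFERENCE_TOTALS = LibraryPair(125_456, 99_632)

# downregulated after light induction (higher relative frequency in D)
REFERENCE_DOWN = [
    ("contig10338_1", "P36618", "Cell division control protein 16, CDC16", 40, 1, 7.48e-10),
    ("contig10470_1", "P20072", "Annexin A7", 68, 2, 1.54e-15),
    ("contig00397_1", "Q5BMR2", "Phospholipase D (PLD1)", 62, 2, 4.31e-14),
    ("contig00525_1", "Q7EYV7", "Poly ADP-ribose polymerase 1 (PARP-1)", 244, 10, 5.19e-49),
    ("contig11321_1", "P38750", "Uncharacterized transporter YHL008C", 24, 1, 5.43e-06),
    ("contig00901_1", "P16064", "Subtilisin inhibitor 1, ASI-I", 21, 1, 2.79e-05),
    ("PpolyN1a03a12", "Q07346", "Glutamate decarboxylase, GAD", 20, 1, 4.80e-05),
    ("PpolyN1a02c07", "P34121", "Coactosin, coaA", 56, 3, 1.07e-11),
    ("contig11574_1", "P39749", "Flap endonuclease 1, FEN-1", 18, 1, 1.41e-04),
    ("contig10414_1", "Q5UNX2", "Putative ankyrin repeat protein, YL715", 90, 5, 8.82e-18),
    ("contig03548_1", "O49286", "F-box/LRR-repeat protein 5, FBL5", 17, 1, 2.42e-04),
    ("contig00369_1", "Q80U58", "Pumilio homolog 2", 17, 1, 2.42e-04),
    ("contig10457_1", "Q8WN03", "Kv channel-interacting protein 2, Kcnip2", 16, 1, 4.12e-04),
    ("contig00264_1", "P13466", "Actin-binding protein 120, ABP-120", 32, 2, 5.26e-07),
    ("contig02333_1", "Q8RWN7", "POLTERGEIST Protein phosphatase 2C 32, PP2C", 15, 1, 7.01e-04),
    ("contig01650_1", "O24496", "Glyoxalase II, Glx II", 15, 1, 7.01e-04),
    ("contig01322_1", "Q94B74", "NADH pyrophosphatase", 15, 1, 7.01e-04),
    ("contig08310_1", "Q10MW3", "Pyruvate decarboxylase isozyme 2, PDC2", 73, 5, 6.84e-14),
    ("contig00558_1", "P18281", "Actobindin", 29, 2, 2.55e-06),
    ("contig11873_1", "O10296", "Apoptosis inhibitor 1, IAP-1", 28, 2, 4.30e-06),
]

# upregulated after light induction (higher relative frequency in L)
REFERENCE_UP = [
    ("PpolyN1d39e07", "O08623", "Sequestosome-1, SQSTM1", 3, 171, 2.03e-56),
    ("contig02685_1", "Q54IV3", "ATP-dependent RNA helicase, DDX42", 1, 37, 7.87e-13),
    ("PpolyN1d106h10", "Q9U1K1", "Spire", 23, 813, 5.40e-250),
    ("PpolyN1a08g07", "O08849", "Regulator of G-protein signaling 2, RGS2", 1, 22, 9.99e-08),
    ("contig05590_1", "Q8H100", "ADP-ribosylation factor GTPase-activating, AGD8", 1, 21, 2.17e-07),
    ("PpolyN1a14d12", "Q07283", "Trichohyalin, TRHY", 1, 20, 4.69e-07),
    ("contig11781_1", "Q55D99", "Serine/threonine-protein kinase, pakA", 2, 34, 8.84e-11),
    ("contig06420_1", "Q9UUG5", "Myosin regulatory light chain 1, MLR1", 1, 17, 4.69e-06),
    ("contig08470_1", "Q54MI7", "Uncharacterized protein DDB_G0285917", 1, 16, 1.01e-05),
    ("contig12553_1", "Q5R826", "Transmembrane protein 63A, TM63A", 20, 308, 1.89e-83),
    ("PpolyN1d18d06", "Q05924", "Dosage-dependent cell cycle regulator 2, DCR2", 1, 15, 2.15e-05),
    ("contig08799_1", "Q43207", "Rotamase, FKBP70", 1, 14, 4.59e-05),
    ("contig12445_1", "Q7S045", "Non-histone chromosomal protein 6, NHP6", 1, 13, 9.76e-05),
    ("contig11110_1", "P54678", "Calcium-transporting ATPase, PAT1", 1, 13, 9.76e-05),
    ("contig08929_1", "Q39572", "Ras-related YPTC6", 1, 13, 9.76e-05),
    ("contig08360_1", "Q6TQE1", "Zinc finger-containing protein 18, NHN1", 1, 12, 2.06e-04),
    ("contig04102_1", "Q9D0C1", "Rab RING finger 7, RR7", 4, 47, 2.86e-13),
    ("contig03233_1", "P06704", "Cell division control protein 31, CDC31", 2, 23, 3.44e-07),
    ("contig02500_1", "Q5UPW6", "Putative FNIP repeat-containing protein, L281", 2, 23, 3.44e-07),
    ("contig08917_1", "Q9PTW9", "Proteasome subunit alpha type-7, PSMA7", 1, 11, 4.35e-04),
]


@pytest.fixture(scope="session")
def reference_totals() -> LibraryPair:
    return REFERENCE_TOTALS


@pytest.fixture(scope="session")
def reference_rows():
    """All 40 reference rows as (contig, accession, desc, hd, hl, p)."""
    return REFERENCE_DOWN + REFERENCE_UP


@pytest.fixture()
def reference_count_table(reference_rows):
    from dgekit.tabio import CountTable, TranscriptCounts

    records = [TranscriptCounts(r[0], r[3], r[4]) for r in reference_rows]
    return CountTable(records, REFERENCE_TOTALS, totals_overridden=True)


@pytest.fixture()
def reference_annotations(reference_rows):
    from dgekit.tabio import AnnotationRecord

    return [AnnotationRecord(r[0], accession=r[1], description=r[2])
            for r in reference_rows]
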